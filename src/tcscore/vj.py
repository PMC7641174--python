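"""V-J combination profiles and the F50 clonal-expansion statistic.

A sample is partitioned into profiles, one per observed (TRBV, TRBJ) gene
pair.  F50 of a profile is the frequency of the clonotype at which the
descending cumulative frequency first reaches 50% of the profile's total:
a large F50 means one or a few clones dominate the V-J combination
(oligoclonal expansion), a tiny F50 means the combination's mass is spread
over many clones.  Frequencies are repertoire-level (not renormalized
within the V-J), and the 50% threshold is relative to the profile's own
total frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .io import RepertoireSample


def vj_key(v_call: str, j_call: str) -> str:
    """Canonical string key of a V-J combination, e.g. 'TRBV27-TRBJ1-5'."""
    return f"{v_call}-{j_call}"


@dataclass(frozen=True)
class VJProfile:
    """All clonotypes of one sample sharing a V-J gene combination.

    Members are (cdr3_aa, repertoire_frequency) pairs sorted by descending
    frequency, ties broken lexicographically by CDR3 so the order is
    deterministic regardless of input row order.
    """

    v_call: str
    j_call: str
    members: tuple[tuple[str, float], ...]

    @property
    def key(self) -> str:
        return vj_key(self.v_call, self.j_call)

    @property
    def n_clonotypes(self) -> int:
        return len(self.members)

    @property
    def total_frequency(self) -> float:
        return float(sum(f for _, f in self.members))

    @property
    def cdr3s(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.members)

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([f for _, f in self.members], dtype=float)

    @staticmethod
    def from_members(v_call: str, j_call: str, members: Sequence[tuple[str, float]]) -> "VJProfile":
        ordered = tuple(sorted(members, key=lambda m: (-m[1], m[0])))
        return VJProfile(v_call, j_call, ordered)


@dataclass(frozen=True)
class F50Value:
    """F50 of one profile: the crossing clonotype's frequency and 1-based rank."""

    value: float
    crossing_index: int


def group_by_vj(sample: RepertoireSample) -> list[VJProfile]:
    """Partition a normalized sample into one profile per observed V-J pair.

    Every clonotype lands in exactly one profile; profiles are returned in
    sorted key order.
    """
    groups: dict[tuple[str, str], list[tuple[str, float]]] = {}
    for c in sample.clonotypes:
        groups.setdefault((c.v_call, c.j_call), []).append((c.cdr3_aa, c.frequency))
    return [
        VJProfile.from_members(v, j, members)
        for (v, j), members in sorted(groups.items())
    ]


def f50(profile: VJProfile) -> F50Value:
    """Frequency of the clonotype whose cumulative frequency reaches half
    the profile total, scanning in descending order.

    The crossing is inclusive: the first clonotype whose cumulative sum is
    >= total/2 is the crossing clonotype.
    """
    if profile.n_clonotypes == 0:
        raise DataError("f50 of an empty profile is undefined")
    freqs = profile.frequencies
    half = freqs.sum() / 2.0
    cum = np.cumsum(freqs)
    # tiny relative slack so that exact-half crossings survive float rounding
    idx = int(np.argmax(cum >= half * (1.0 - 1e-12)))
    return F50Value(value=float(freqs[idx]), crossing_index=idx + 1)


def vj_feature_table(sample: RepertoireSample) -> pd.DataFrame:
    """Per-VJ summary table: v_call, j_call, n_clonotypes, total_frequency, f50."""
    rows = []
    for p in group_by_vj(sample):
        rows.append(
            {
                "v_call": p.v_call,
                "j_call": p.j_call,
                "n_clonotypes": p.n_clonotypes,
                "total_frequency": p.total_frequency,
                "f50": f50(p).value,
            }
        )
    return pd.DataFrame(rows, columns=["v_call", "j_call", "n_clonotypes", "total_frequency", "f50"])
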