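"""Tissue/blood repertoire overlap and Morisita-Horn similarity.

Two analyses on paired samples from the same patient: (i) partition of
tissue clonotypes at a frequency threshold (default 0.001) into
blood-overlapping vs tissue-specific, with cumulative frequencies per
bin; (ii) the abundance-weighted Morisita-Horn similarity index over rank
windows of either sample (all clonotypes, top 1-20, ranks 21-1000, ...),
computed "in both directions" by ranking on each sample in turn.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import DataError
from .io import KeyMode, RepertoireSample, clonotype_key


def morisita_horn(p: Mapping, q: Mapping) -> float:
    """Morisita-Horn similarity of two abundance mappings, in [0, 1].

    MH = 2 sum_i p_i q_i / ((sum p_i^2 / P^2 + sum q_i^2 / Q^2) * P * Q)
    with P = sum p, Q = sum q; invariant to rescaling either mapping.
    """
    if not p or not q:
        raise DataError("Morisita-Horn of an empty mapping is undefined")
    keys = set(p) | set(q)
    pv = np.array([p.get(k, 0.0) for k in keys], dtype=float)
    qv = np.array([q.get(k, 0.0) for k in keys], dtype=float)
    if (pv < 0).any() or (qv < 0).any():
        raise DataError("abundances must be non-negative")
    P, Q = pv.sum(), qv.sum()
    if P == 0 or Q == 0:
        raise DataError("Morisita-Horn of an all-zero mapping is undefined")
    num = 2.0 * float(pv @ qv)
    den = (float(pv @ pv) / P**2 + float(qv @ qv) / Q**2) * P * Q
    return num / den


@dataclass(frozen=True)
class MHScore:
    value: float
    direction: str  # sample id whose ranking defined the clonotype window
    rank_window: tuple[int, int]


def _ranked_keys(sample: RepertoireSample, mode: KeyMode) -> list[tuple]:
    """Clonotype keys by descending frequency, ties lexicographic."""
    return [
        clonotype_key(c, mode)
        for c in sorted(sample.clonotypes, key=lambda c: (-c.frequency, c.cdr3_aa, c.v_call, c.j_call))
    ]


def directional_topk_mh(
    ref: RepertoireSample,
    other: RepertoireSample,
    rank_lo: int = 1,
    rank_hi: int | None = None,
    mode: KeyMode = "vj_cdr3aa",
) -> MHScore:
    """Morisita-Horn over the clonotypes ranked [rank_lo, rank_hi] in ``ref``.

    The window is defined on the reference sample's descending-frequency
    ranking; frequencies of the selected clonotypes are taken raw from
    each sample (0 if absent in the other) without renormalization, so
    directionality comes purely from the window choice.
    """
    if rank_hi is None:
        rank_hi = len(ref.clonotypes)
    if not (1 <= rank_lo <= rank_hi):
        raise DataError(f"invalid rank window ({rank_lo}, {rank_hi})")
    ranked = _ranked_keys(ref, mode)
    if rank_lo > len(ranked):
        raise DataError(
            f"rank window starts at {rank_lo} but {ref.sample_id} has only {len(ranked)} clonotypes"
        )
    window = ranked[rank_lo - 1 : rank_hi]
    ref_freq = ref.frequencies(mode)
    other_freq = other.frequencies(mode)
    p = {k: ref_freq[k] for k in window}
    q = {k: other_freq.get(k, 0.0) for k in window}
    if sum(q.values()) == 0.0:
        value = 0.0  # disjoint supports within the window
    else:
        value = morisita_horn(p, q)
    return MHScore(value=value, direction=ref.sample_id, rank_window=(rank_lo, rank_hi))


@dataclass(frozen=True)
class BinStats:
    n_overlapping: int
    n_specific: int
    cum_freq_overlapping: float
    cum_freq_specific: float

    @property
    def n_total(self) -> int:
        return self.n_overlapping + self.n_specific


@dataclass(frozen=True)
class OverlapPartition:
    """Tissue clonotypes split by frequency bin and blood presence."""

    over: BinStats
    below: BinStats
    threshold: float

    @property
    def n_total(self) -> int:
        return self.over.n_total + self.below.n_total


def overlap_partition(
    tissue: RepertoireSample,
    blood: RepertoireSample,
    threshold: float = 0.001,
    mode: KeyMode = "vj_cdr3aa",
) -> OverlapPartition:
    """Bin tissue clonotypes by frequency (> threshold strict vs <=) and
    split each bin by presence of the clonotype key in blood."""
    if not (0.0 < threshold < 1.0):
        raise DataError("threshold must be in (0, 1)")
    blood_keys = set(blood.frequencies(mode))
    stats = {True: [0, 0, 0.0, 0.0], False: [0, 0, 0.0, 0.0]}  # over? -> [n_ov, n_sp, f_ov, f_sp]
    for c in tissue.clonotypes:
        over = c.frequency > threshold
        shared = clonotype_key(c, mode) in blood_keys
        bucket = stats[over]
        if shared:
            bucket[0] += 1
            bucket[2] += c.frequency
        else:
            bucket[1] += 1
            bucket[3] += c.frequency
    return OverlapPartition(
        over=BinStats(*stats[True][:2], *stats[True][2:]),
        below=BinStats(*stats[False][:2], *stats[False][2:]),
        threshold=threshold,
    )
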