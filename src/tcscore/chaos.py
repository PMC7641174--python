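"""Weighted-Hamming CDR3 distances and the entropy-variability chaos score.

The distance between two CDR3 amino-acid sequences is a TCRdist-style
integer: per aligned position, identity costs 0, a substitution costs
``min(cap, cap - BLOSUM62(a, b))`` (so conservative substitutions are
cheap and dissimilar ones saturate at the cap), and a gap against a
residue costs ``gap_cost``.  Unequal lengths are aligned deterministically
by anchoring the first ceil(n/2) residues of the shorter sequence on the
left and the last floor(n/2) on the right, with one contiguous gap block
in the middle — the convention TCRdist uses for the CDR3 loop.

The chaos of a V-J combination summarizes the multiset of pairwise
distances among its unique CDR3s: E is the Shannon entropy (bits) of the
distance-value distribution, V the number of distinct distance values,
and chaos (by default) their product E*V.  Homologous, antigen-focused
CDR3 sets concentrate on few distance values and score low; diverse sets
score high.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Mapping

import numpy as np
from Bio.Align import substitution_matrices

from .errors import ConfigurationError, InvalidSequenceError
from .io import STANDARD_AA
from .vj import VJProfile

GAP_CODE = 26  # codes 0..25 are 'A'..'Z'; 26 is the gap symbol

ChaosFormula = Literal["product", "sum", "entropy_only"]


@dataclass(frozen=True)
class DistanceParams:
    """Parameters of the weighted-Hamming CDR3 distance.

    subsample_cap bounds the number of unique CDR3s entering the pairwise
    computation of one V-J; larger profiles are subsampled uniformly with
    subsample_seed (exact computation is recovered whenever
    subsample_cap >= n_clonotypes).
    """

    matrix: str = "BLOSUM62"
    cap: int = 4
    gap_cost: int = 4
    subsample_cap: int = 2000
    subsample_seed: int = 0

    def __post_init__(self) -> None:
        if self.cap <= 0 or self.gap_cost <= 0:
            raise ConfigurationError("cap and gap_cost must be positive")
        if self.subsample_cap < 2:
            raise ConfigurationError("subsample_cap must be >= 2")


@lru_cache(maxsize=8)
def _cost_matrix(matrix: str, cap: int, gap_cost: int) -> np.ndarray:
    """27x27 integer per-position cost table over letter codes + gap."""
    subs = substitution_matrices.load(matrix)
    cost = np.zeros((27, 27), dtype=np.int64)
    for a in STANDARD_AA:
        for b in STANDARD_AA:
            if a == b:
                continue
            cost[ord(a) - 65, ord(b) - 65] = min(cap, cap - int(subs[a, b]))
    cost[GAP_CODE, :27] = gap_cost
    cost[:27, GAP_CODE] = gap_cost
    cost[GAP_CODE, GAP_CODE] = 0
    return cost


def _encode(seq: str) -> np.ndarray:
    if not seq or not set(seq) <= STANDARD_AA:
        raise InvalidSequenceError(f"invalid CDR3 sequence: {seq!r}")
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).astype(np.intp) - 65


def _pad_middle(codes: np.ndarray, target_len: int) -> np.ndarray:
    """Insert a contiguous gap block after the first ceil(n/2) residues."""
    n = codes.shape[-1]
    if n == target_len:
        return codes
    left = (n + 1) // 2
    gap_block = np.full(codes.shape[:-1] + (target_len - n,), GAP_CODE, dtype=codes.dtype)
    return np.concatenate([codes[..., :left], gap_block, codes[..., left:]], axis=-1)


def cdr3_distance(a: str, b: str, params: DistanceParams = DistanceParams()) -> int:
    """Integer weighted-Hamming distance between two CDR3 sequences."""
    ca, cb = _encode(a), _encode(b)
    if len(ca) > len(cb):
        ca, cb = cb, ca
    ca = _pad_middle(ca, len(cb))
    cost = _cost_matrix(params.matrix, params.cap, params.gap_cost)
    return int(cost[ca, cb].sum())


@dataclass(frozen=True)
class DistanceDistribution:
    """Multiset of pairwise distances within one V-J, as value -> pair count."""

    counts: Mapping[int, int] = field(default_factory=dict)
    n_pairs: int = 0
    subsampled: bool = False

    def values(self) -> np.ndarray:
        return np.array(sorted(self.counts), dtype=int)

    def pair_counts(self) -> np.ndarray:
        return np.array([self.counts[d] for d in sorted(self.counts)], dtype=int)


@dataclass(frozen=True)
class EVScore:
    """Entropy (bits), variability (distinct distances) and their chaos combination."""

    entropy_bits: float
    variability: int
    chaos: float
    degenerate: bool = False


def pairwise_distance_distribution(
    profile: VJProfile, params: DistanceParams = DistanceParams()
) -> DistanceDistribution:
    """Distance multiset over all unordered pairs of unique CDR3s in a profile.

    Each unique CDR3 enters once, unweighted by clone size.  Profiles larger
    than ``subsample_cap`` are reduced to a seeded uniform subsample.
    """
    cdr3s = list(profile.cdr3s)
    subsampled = False
    if len(cdr3s) > params.subsample_cap:
        rng = np.random.default_rng(params.subsample_seed)
        idx = rng.choice(len(cdr3s), size=params.subsample_cap, replace=False)
        cdr3s = [cdr3s[i] for i in np.sort(idx)]
        subsampled = True
    if len(cdr3s) < 2:
        return DistanceDistribution(counts={}, n_pairs=0, subsampled=subsampled)

    cost = _cost_matrix(params.matrix, params.cap, params.gap_cost)
    by_len: dict[int, np.ndarray] = {}
    for length in sorted({len(s) for s in cdr3s}):
        group = [s for s in cdr3s if len(s) == length]
        by_len[length] = np.stack([_encode(s) for s in group])

    counter: Counter[int] = Counter()
    lengths = sorted(by_len)
    for i, l1 in enumerate(lengths):
        a = by_len[l1]
        # same-length pairs: no gaps
        if a.shape[0] > 1:
            iu, ju = np.triu_indices(a.shape[0], k=1)
            d = cost[a[iu], a[ju]].sum(axis=1)
            counter.update(d.tolist())
        # cross-length pairs: pad the shorter group to the longer length
        for l2 in lengths[i + 1 :]:
            b = by_len[l2]
            ap = _pad_middle(a, l2)
            d = cost[ap[:, None, :], b[None, :, :]].sum(axis=2)
            counter.update(d.ravel().tolist())

    n_pairs = len(cdr3s) * (len(cdr3s) - 1) // 2
    return DistanceDistribution(counts=dict(counter), n_pairs=n_pairs, subsampled=subsampled)


def ev_score(dist: DistanceDistribution, chaos_formula: ChaosFormula = "product") -> EVScore:
    """Entropy-variability score of a distance distribution.

    E = -sum p_d log2 p_d over distance values, V = number of distinct
    values; chaos = E*V (product), E+V (sum) or E (entropy_only).  An
    empty distribution (fewer than two CDR3s) is flagged degenerate with
    E = V = chaos = 0.
    """
    if chaos_formula not in ("product", "sum", "entropy_only"):
        raise ConfigurationError(f"unknown chaos formula: {chaos_formula!r}")
    if dist.n_pairs == 0:
        return EVScore(entropy_bits=0.0, variability=0, chaos=0.0, degenerate=True)
    p = dist.pair_counts() / dist.n_pairs
    entropy = float(-(p * np.log2(p)).sum())
    v = len(dist.counts)
    if chaos_formula == "product":
        chaos = entropy * v
    elif chaos_formula == "sum":
        chaos = entropy + v
    else:
        chaos = entropy
    return EVScore(entropy_bits=entropy, variability=v, chaos=float(chaos))
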