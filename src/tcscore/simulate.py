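"""Seeded synthetic TCR-beta cohorts with the structure the pipeline assumes.

Each sample is a blood repertoire: clone sizes drawn iid from a capped
discrete power law (Zipf exponent 1.5 — heavy-tailed, so a handful of
naturally expanded clones emerge in random V-Js of every sample), V and J
gene usage drawn once per cohort from Dirichlet distributions over 48
TRBV x 13 TRBJ genes, and CDR3s as random C...F-framed peptides of
length 9-18.

Disease classes differ only inside a small set of "signal" V-J
combinations (default 13, the most-used combinations so they are present
in every sample).  With per-V-J penetrance 0.9 an affected sample
receives, in each signal V-J, an expanded clone (frequency 0.01-0.06,
raising F50) and/or a homology cluster (30 CDR3s within 2 substitutions
of a seed, lowering the chaos of the distance distribution).  GH_to_GO
samples carry the same signal at 0.7x penetrance.  Healthy-comparator
(GH) samples carry no planted signal; their oligoclonality is whatever
the heavy-tailed clone-size law produces.

Follow-up emulation: progressors get gamma-distributed event times with
median 6.5 months; everyone else is censored at 18 months.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .errors import ConfigurationError
from .io import CohortMetadata, RepertoireSample, sample_from_counts, write_airr, write_metadata
from .survival import DEFAULT_HORIZON_MONTHS, SurvivalRecord
from .vj import vj_key

AA_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

TRBV_GENES = (
    "TRBV2", "TRBV3-1", "TRBV4-1", "TRBV4-2", "TRBV4-3",
    "TRBV5-1", "TRBV5-4", "TRBV5-5", "TRBV5-6", "TRBV5-8",
    "TRBV6-1", "TRBV6-2", "TRBV6-3", "TRBV6-4", "TRBV6-5",
    "TRBV6-6", "TRBV6-8", "TRBV6-9", "TRBV7-2", "TRBV7-3",
    "TRBV7-4", "TRBV7-6", "TRBV7-7", "TRBV7-8", "TRBV7-9",
    "TRBV9", "TRBV10-1", "TRBV10-2", "TRBV10-3", "TRBV11-1",
    "TRBV11-2", "TRBV11-3", "TRBV12-3", "TRBV12-4", "TRBV12-5",
    "TRBV13", "TRBV14", "TRBV15", "TRBV16", "TRBV18",
    "TRBV19", "TRBV20-1", "TRBV24-1", "TRBV25-1", "TRBV27",
    "TRBV28", "TRBV29-1", "TRBV30",
)
TRBJ_GENES = (
    "TRBJ1-1", "TRBJ1-2", "TRBJ1-3", "TRBJ1-4", "TRBJ1-5", "TRBJ1-6",
    "TRBJ2-1", "TRBJ2-2", "TRBJ2-3", "TRBJ2-4", "TRBJ2-5", "TRBJ2-6", "TRBJ2-7",
)

SIGNAL_CLASSES = ("GO", "GH_to_GO")


@dataclass(frozen=True)
class SimulationConfig:
    n_GO: int = 33
    n_GH: int = 37
    n_GH_to_GO: int = 0
    clonotypes_per_sample: int = 20_000
    zipf_exponent: float = 1.5
    max_clone_count: int = 1000
    n_signal_vjs: int = 13
    expansion_freq_range: tuple[float, float] = (0.01, 0.06)
    cluster_size: int = 30
    cluster_max_subs: int = 2
    effect_penetrance: float = 0.9
    gh_to_go_attenuation: float = 0.7
    inject_expansion: bool = True
    inject_cluster: bool = True
    cdr3_length_range: tuple[int, int] = (9, 18)
    followup_shape: float = 2.0
    followup_median_months: float = 6.5
    followup_censor_months: float = DEFAULT_HORIZON_MONTHS
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.zipf_exponent <= 1.0:
            raise ConfigurationError("zipf_exponent must be > 1")
        lo, hi = self.expansion_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError("expansion_freq_range must be ordered within (0, 1)")
        lo, hi = self.cdr3_length_range
        if not (3 <= lo <= hi):
            raise ConfigurationError("cdr3_length_range must be ordered and >= 3")
        if not (0.0 <= self.effect_penetrance <= 1.0):
            raise ConfigurationError("effect_penetrance must be a probability")


@dataclass(frozen=True)
class CohortContext:
    """Cohort-level randomness shared by all samples: gene usage and signal V-Js."""

    v_probs: np.ndarray
    j_probs: np.ndarray
    signal_vjs: tuple[str, ...]


@dataclass
class Cohort:
    samples: list[RepertoireSample]
    metadata: CohortMetadata
    signal_vjs: tuple[str, ...]
    master_seed: int

    @property
    def labels(self) -> dict[str, str]:
        return dict(zip(self.metadata.table["sample_id"], self.metadata.table["label"]))


def cohort_context(config: SimulationConfig) -> CohortContext:
    """Draw the cohort's V/J usage (Dirichlet) and pick the signal V-Js.

    Signal combinations are the ``n_signal_vjs`` most-used V-J pairs, so
    every simulated sample observes them.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.master_seed, 0xC0]))
    v_probs = rng.dirichlet(np.ones(len(TRBV_GENES)))
    j_probs = rng.dirichlet(np.ones(len(TRBJ_GENES)))
    joint = np.outer(v_probs, j_probs)
    flat = joint.ravel()
    top = np.argsort(-flat)[: config.n_signal_vjs]
    signal = tuple(
        vj_key(TRBV_GENES[i // len(TRBJ_GENES)], TRBJ_GENES[i % len(TRBJ_GENES)]) for i in top
    )
    return CohortContext(v_probs=v_probs, j_probs=j_probs, signal_vjs=signal)


def _random_cdr3s(rng: np.random.Generator, lengths: np.ndarray) -> list[str]:
    """C...F-framed random peptides with the given total lengths."""
    middle = lengths - 2
    letters = AA_ALPHABET[rng.integers(0, len(AA_ALPHABET), size=int(middle.sum()))]
    out, pos = [], 0
    for m in middle:
        out.append("C" + "".join(letters[pos : pos + m]) + "F")
        pos += m
    return out


def _mutate_cdr3(rng: np.random.Generator, seed_cdr3: str, max_subs: int) -> str:
    """Substitute 1..max_subs middle positions of a C...F-framed CDR3."""
    body = list(seed_cdr3[1:-1])
    k = int(rng.integers(1, max_subs + 1))
    positions = rng.choice(len(body), size=min(k, len(body)), replace=False)
    for p in positions:
        body[p] = str(rng.choice(AA_ALPHABET))
    return seed_cdr3[0] + "".join(body) + seed_cdr3[-1]


def simulate_repertoire(
    config: SimulationConfig,
    class_label: str,
    seed: int,
    sample_id: str | None = None,
    context: CohortContext | None = None,
    tissue: str = "blood",
) -> RepertoireSample:
    """One synthetic blood repertoire; signal classes get planted V-J effects."""
    ctx = context or cohort_context(config)
    rng = np.random.default_rng(seed)
    n = config.clonotypes_per_sample
    lo, hi = config.cdr3_length_range

    counts = np.minimum(rng.zipf(config.zipf_exponent, size=n), config.max_clone_count)
    v_idx = rng.choice(len(TRBV_GENES), size=n, p=ctx.v_probs)
    j_idx = rng.choice(len(TRBJ_GENES), size=n, p=ctx.j_probs)
    lengths = rng.integers(lo, hi + 1, size=n)
    cdr3s = _random_cdr3s(rng, lengths)

    records: list[tuple[str, str, str, int]] = [
        (TRBV_GENES[v_idx[i]], TRBJ_GENES[j_idx[i]], cdr3s[i], int(counts[i])) for i in range(n)
    ]

    if class_label in SIGNAL_CLASSES:
        penetrance = config.effect_penetrance
        if class_label == "GH_to_GO":
            penetrance *= config.gh_to_go_attenuation
        base_total = int(counts.sum())
        cluster_records: list[tuple[str, str, str, int]] = []
        expansions: list[tuple[str, str, float]] = []  # (v, j, target frequency)
        for key in ctx.signal_vjs:
            if rng.random() >= penetrance:
                continue
            # vj_key is V + "-" + J; J names start with "TRBJ"
            v, j = key.split("-TRBJ")
            j = "TRBJ" + j
            if config.inject_cluster:
                seed_cdr3 = _random_cdr3s(rng, np.array([int(rng.integers(lo, hi + 1))]))[0]
                for _ in range(config.cluster_size):
                    cluster_records.append(
                        (v, j, _mutate_cdr3(rng, seed_cdr3, config.cluster_max_subs),
                         int(rng.integers(1, 6)))
                    )
            if config.inject_expansion:
                f = rng.uniform(*config.expansion_freq_range)
                expanded = _random_cdr3s(rng, np.array([int(rng.integers(lo, hi + 1))]))[0]
                expansions.append((v, j, f, expanded))  # type: ignore[arg-type]
        records.extend(cluster_records)
        total = base_total + sum(r[3] for r in cluster_records)
        f_sum = sum(e[2] for e in expansions)
        if f_sum >= 1.0:
            raise ConfigurationError("planted expansion frequencies sum to >= 1")
        for v, j, f, expanded in expansions:  # type: ignore[misc]
            count = max(1, round(f * total / (1.0 - f_sum)))
            records.append((v, j, expanded, count))

    return sample_from_counts(
        sample_id or f"sim{seed}", records, tissue=tissue, label=class_label
    ).normalized()


def _sample_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n, dtype=np.uint32) >> np.uint32(1)]


def simulate_cohort(
    config: SimulationConfig,
    outdir: str | Path | None = None,
    context: CohortContext | None = None,
) -> Cohort:
    """Simulate the full cohort; optionally write AIRR TSVs, metadata CSV
    and the ground-truth JSON (signal V-Js, labels, master seed).

    Pass a shared ``context`` when several cohorts (training, test,
    validation) are drawn from the same study population, so they share
    gene usage and signal V-Js while their sample seeds differ.
    """
    ctx = context or cohort_context(config)
    labels = (["GO"] * config.n_GO + ["GH"] * config.n_GH + ["GH_to_GO"] * config.n_GH_to_GO)
    seeds = _sample_seeds(config.master_seed, len(labels))
    samples = []
    rows = []
    for i, (label, seed) in enumerate(zip(labels, seeds)):
        sid = f"S{i + 1:03d}"
        samples.append(
            simulate_repertoire(config, label, seed, sample_id=sid, context=ctx)
        )
        rows.append(
            {"sample_id": sid, "label": label, "tissue": "blood",
             "followup_months": np.nan, "go_event": np.nan}
        )
    metadata = CohortMetadata(pd.DataFrame(rows, columns=list(CohortMetadata.COLUMNS)))
    cohort = Cohort(samples=samples, metadata=metadata,
                    signal_vjs=ctx.signal_vjs, master_seed=config.master_seed)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for s in samples:
            write_airr(s, outdir / f"{s.sample_id}.tsv")
        write_metadata(metadata, outdir / "metadata.csv")
        truth = {
            "signal_vjs": list(ctx.signal_vjs),
            "labels": cohort.labels,
            "master_seed": config.master_seed,
            "config": asdict(config),
        }
        (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return cohort


def simulate_paired_tissue_blood(
    config: SimulationConfig, seed: int
) -> tuple[RepertoireSample, RepertoireSample]:
    """A thyroid/blood pair from one patient.

    The thyroid repertoire is derived from the blood clone pool with the
    top blood clones enriched, a random half of the tail retained, and
    tissue-private clones added at count 1 — scaled so every thyroid
    clone above frequency 0.001 is guaranteed present in blood.
    """
    blood = simulate_repertoire(config, "unlabeled", seed, sample_id=f"blood{seed}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x71]))
    ranked = sorted(blood.clonotypes, key=lambda c: (-c.frequency, c.cdr3_aa))
    records: list[tuple[str, str, str, int]] = []
    n_top = min(50, len(ranked))
    for c in ranked[:n_top]:
        enrich = rng.uniform(3.0, 15.0)
        records.append((c.v_call, c.j_call, c.cdr3_aa, max(1, round(c.count * enrich))))
    for c in ranked[n_top:]:
        if rng.random() < 0.5:
            records.append((c.v_call, c.j_call, c.cdr3_aa, c.count))
    shared_total = sum(r[3] for r in records)
    n_private = max(1, len(ranked) // 3)
    # private clones sit at count 1; inflate shared counts if needed so that
    # 1 / total <= 0.001, keeping every over-threshold thyroid clone shared
    total = shared_total + n_private
    if 1.0 / total > 0.001:
        factor = int(np.ceil(1.0 / (0.001 * total)))
        records = [(v, j, c, n * factor) for v, j, c, n in records]
    lo, hi = config.cdr3_length_range
    lengths = rng.integers(lo, hi + 1, size=n_private)
    private_cdr3s = _random_cdr3s(rng, lengths)
    v_idx = rng.integers(0, len(TRBV_GENES), size=n_private)
    j_idx = rng.integers(0, len(TRBJ_GENES), size=n_private)
    for i in range(n_private):
        records.append((TRBV_GENES[v_idx[i]], TRBJ_GENES[j_idx[i]], private_cdr3s[i], 1))
    thyroid = sample_from_counts(f"thyroid{seed}", records, tissue="thyroid")
    return thyroid, blood


def simulate_followup(
    assignments: pd.DataFrame,
    config: SimulationConfig,
    seed: int,
) -> list[SurvivalRecord]:
    """Follow-up records for a cohort table with columns
    sample_id, label (truth), group (e.g. prediction).

    True progressors (label GH_to_GO or GO) draw gamma event times with
    the configured median; times beyond the censoring horizon, and all
    non-progressors, are censored at the horizon.
    """
    rng = np.random.default_rng(seed)
    scale = config.followup_median_months / gamma_dist.ppf(0.5, a=config.followup_shape)
    records = []
    for row in assignments.itertuples():
        progressor = row.label in SIGNAL_CLASSES
        if progressor:
            t = float(rng.gamma(config.followup_shape, scale))
            if t >= config.followup_censor_months or t <= 0:
                records.append(SurvivalRecord(row.sample_id, row.group,
                                              config.followup_censor_months, False))
            else:
                records.append(SurvivalRecord(row.sample_id, row.group, t, True))
        else:
            records.append(SurvivalRecord(row.sample_id, row.group,
                                          config.followup_censor_months, False))
    return records


def content_hash(sample: RepertoireSample) -> str:
    """Stable digest of a sample's clonotype content (for reproducibility checks)."""
    h = hashlib.sha256()
    for c in sample.clonotypes:
        h.update(f"{c.v_call}|{c.j_call}|{c.cdr3_aa}|{c.count}\n".encode())
    return h.hexdigest()
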