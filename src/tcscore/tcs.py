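"""TCS: the clonal-expansion / chaos ratio per V-J, and the cohort feature matrix.

TCS of a V-J combination is F50 divided by chaos.  Antigen-driven
activation raises F50 (expansion) and/or lowers chaos (homologous CDR3s),
so either mechanism raises TCS.  Chaos is floored at ``chaos_floor`` so
degenerate combinations (a single clonotype, or a single distance value)
yield a finite score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .chaos import DistanceParams, EVScore, ev_score, pairwise_distance_distribution
from .errors import ConfigurationError, DataError
from .io import RepertoireSample
from .vj import f50, group_by_vj


@dataclass(frozen=True)
class TCSConfig:
    chaos_floor: float = 1.0
    min_clonotypes: int = 1
    missing_value_policy: Literal["zero", "nan"] = "zero"
    chaos_formula: str = "product"

    def __post_init__(self) -> None:
        if self.chaos_floor <= 0:
            raise ConfigurationError("chaos_floor must be positive")
        if self.missing_value_policy not in ("zero", "nan"):
            raise ConfigurationError(f"unknown missing_value_policy: {self.missing_value_policy!r}")


@dataclass
class TCSFeatureMatrix:
    """Samples x V-J matrix of TCS values with per-sample class labels."""

    values: pd.DataFrame  # index: sample ids, columns: sorted VJ keys
    labels: pd.Series  # index: sample ids

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise DataError("duplicate VJ keys in feature matrix")
        if not self.values.index.equals(self.labels.index):
            raise DataError("feature matrix rows and labels are misaligned")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def vj_universe(self) -> list[str]:
        return list(self.values.columns)


def tcs_of_vj(f50_value: float, ev: EVScore, config: TCSConfig = TCSConfig()) -> float:
    """TCS = F50 / max(chaos, chaos_floor)."""
    if f50_value < 0:
        raise DataError("F50 must be non-negative")
    return f50_value / max(ev.chaos, config.chaos_floor)


def sample_tcs_vector(
    sample: RepertoireSample,
    params: DistanceParams = DistanceParams(),
    config: TCSConfig = TCSConfig(),
) -> dict[str, float]:
    """One TCS value per V-J observed in the sample.

    Pipeline per V-J: F50 of the descending frequency profile, pairwise
    CDR3 distance distribution, entropy-variability chaos, ratio.
    """
    out: dict[str, float] = {}
    for profile in group_by_vj(sample):
        if profile.n_clonotypes < config.min_clonotypes:
            continue
        ev = ev_score(
            pairwise_distance_distribution(profile, params),
            chaos_formula=config.chaos_formula,  # type: ignore[arg-type]
        )
        out[profile.key] = tcs_of_vj(f50(profile).value, ev, config)
    return out


def build_feature_matrix(
    tcs_vectors: Mapping[str, Mapping[str, float]],
    labels: Mapping[str, str],
    universe: Sequence[str] | None = None,
    config: TCSConfig = TCSConfig(),
) -> TCSFeatureMatrix:
    """Assemble per-sample TCS vectors into a samples x V-J matrix.

    The V-J universe is the union of combinations observed across the
    cohort (default) or an explicit list; combinations absent from a
    sample are filled with 0 (no expansion evidence) or NaN per
    ``missing_value_policy``.  Column order is the sorted VJ key,
    independent of sample order.
    """
    if len(tcs_vectors) < 2:
        raise DataError("a cohort feature matrix needs >= 2 samples")
    if universe is None:
        seen: set[str] = set()
        for vec in tcs_vectors.values():
            seen.update(vec)
        universe = sorted(seen)
    else:
        universe = list(universe)
    if not universe:
        raise DataError("empty VJ universe")
    fill = 0.0 if config.missing_value_policy == "zero" else np.nan
    sample_ids = list(tcs_vectors)
    values = pd.DataFrame(
        [[tcs_vectors[s].get(vj, fill) for vj in universe] for s in sample_ids],
        index=pd.Index(sample_ids, name="sample_id"),
        columns=universe,
        dtype=float,
    )
    label_series = pd.Series({s: labels[s] for s in sample_ids}, name="label").loc[sample_ids]
    return TCSFeatureMatrix(values=values, labels=label_series)


def matrix_to_tsv(matrix: TCSFeatureMatrix, path) -> None:
    df = matrix.values.copy()
    df.insert(0, "label", matrix.labels)
    df.to_csv(path, sep="\t")


def matrix_from_tsv(path) -> TCSFeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = df.pop("label")
    return TCSFeatureMatrix(values=df.astype(float), labels=labels)
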