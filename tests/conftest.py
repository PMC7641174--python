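import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tcscore.io import RepertoireSample, sample_from_counts

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def toy_sample() -> RepertoireSample:
    """Five clonotypes across three V-J combinations, counts 10/5/3/1/1."""
    return sample_from_counts(
        "toy",
        [
            ("TRBV27", "TRBJ1-5", "CASSLGETQYF", 10),
            ("TRBV27", "TRBJ1-5", "CASSFGETQYF", 5),
            ("TRBV28", "TRBJ2-7", "CASRDRGYEQYF", 3),
            ("TRBV28", "TRBJ2-7", "CASRDRNYEQYF", 1),
            ("TRBV9", "TRBJ1-1", "CASSVGNTEAFF", 1),
        ],
    )


@pytest.fixture
def airr_tsv(tmp_path):
    """Write a small AIRR Rearrangement TSV and return its path."""

    def _write(rows, name="sample.tsv", header=("junction_aa", "v_call", "j_call", "duplicate_count")):
        path = tmp_path / name
        lines = ["\t".join(header)]
        lines += ["\t".join(str(x) for x in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


def random_cdr3(rng: np.random.Generator, length: int | None = None) -> str:
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    n = length or int(rng.integers(6, 19))
    return "".join(alphabet[i] for i in rng.integers(0, 20, n))
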