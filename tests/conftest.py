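from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from binbalance import BinID, CoverageProfile, ReferenceDict, simulate_mapped_reads
from binbalance.synthetic import write_sam

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def small_ref() -> ReferenceDict:
    """Three chromosomes, 20/12/6 bins at the default 5000 bp bin width."""
    return ReferenceDict([("chr1", 100_000), ("chr2", 60_000), ("chr3", 30_000)])


@pytest.fixture
def ref_header_path(small_ref, tmp_path) -> Path:
    path = tmp_path / "ref.sam"
    path.write_text("\n".join(small_ref.to_sam_header_lines()) + "\n")
    return path


@pytest.fixture
def skewed_sam(small_ref, tmp_path):
    """A 5000-record SAM file with a 20x coverage hotspot, plus ground truth."""
    profile = CoverageProfile(seed=7, hotspots=[(BinID(0, 2), 20.0)])
    lines, truth = simulate_mapped_reads(
        small_ref, profile, 5000, n_unmapped=10
    )
    path = write_sam(lines, tmp_path / "reads.sam")
    return path, truth
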