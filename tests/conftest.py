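import pytest

from ampsnv.counts_io import BASES, PositionKey, SampleCounts, StrandCounts
from ampsnv.simulate import (
    default_het_sites,
    default_panel_positions,
    heterogeneous_profile,
    simulate_normals,
)


def make_record(ref: str, depth_fwd: int, depth_rev: int, **alt_counts) -> StrandCounts:
    """Build a consistent StrandCounts from non-reference counts.

    Keyword arguments like ``C_fwd=2, C_rev=1`` give the non-reference
    counts; the reference base absorbs the remaining depth.
    """
    alt_fwd = {b: 0 for b in BASES}
    alt_rev = {b: 0 for b in BASES}
    for name, value in alt_counts.items():
        base, strand = name.split("_")
        (alt_fwd if strand == "fwd" else alt_rev)[base] = value
    alt_fwd[ref] = depth_fwd - sum(alt_fwd[b] for b in BASES if b != ref)
    alt_rev[ref] = depth_rev - sum(alt_rev[b] for b in BASES if b != ref)
    return StrandCounts(depth_fwd, depth_rev, alt_fwd, alt_rev)


def single_position_sample(
    sample_id: str,
    key: PositionKey,
    depth_fwd: int,
    depth_rev: int,
    **alt_counts,
) -> SampleCounts:
    return SampleCounts(
        sample_id=sample_id,
        records={key: make_record(key.ref, depth_fwd, depth_rev, **alt_counts)},
    )


@pytest.fixture(scope="session")
def small_cohort():
    """60 simulated normals over 200 positions with heterogeneous noise and
    10 germline het sites at 30% carrier frequency; shared across tests."""
    positions = default_panel_positions(200, seed=11)
    profile = heterogeneous_profile(positions, seed=12)
    het_sites = default_het_sites(positions, n_sites=10, carrier_freq=0.3, seed=13)
    cohort = simulate_normals(profile, 60, seed=14, het_sites=het_sites)
    return {
        "positions": positions,
        "profile": profile,
        "het_sites": het_sites,
        "cohort": cohort,
    }
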