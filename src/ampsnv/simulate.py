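"""Synthetic normal cohorts, spiked variants and the two benchmark protocols.

The generator emulates amplicon deep sequencing of a panel of normal
samples: per-strand depths follow a negative binomial around a mean depth
(uneven amplicon coverage), and per (position, allele, strand) the number of
error-driven reads is Binomial(depth, e_true) for a position-specific true
error rate. Transition-type substitutions (A>G/T>C and, less so, C>T/G>A)
receive elevated rates, mirroring the systematic error structure of
semiconductor sequencing, and a small fraction of "hot" positions carries
an order-of-magnitude higher rate. Germline heterozygous variants are
simulated as carrier samples whose allele draws use a 50% rate.

Two experiment drivers are provided:

* a self-consistency protocol — train the error model on a random subset of
  M normals, call variants on the held-out normals, and label alleles with
  VAF >= 20% as true positives and everything below as negatives; repeated
  with fresh subsets and summarised by median FDR/TPR;
* a synthetic-variant protocol — spike alleles at fixed depth COV (split
  evenly across strands) and fixed VAF into every panel position and measure
  the fraction recovered as PASS calls (TPR; every spike is a positive, so
  no FDR exists here).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special

from .caller import CallerConfig, ObservedAllele, call_variants
from .counts_io import BASES, PositionKey, SampleCounts, StrandCounts
from .error_model import (
    ErrorModel,
    ErrorModelConfig,
    constant_error_model,
    estimate_errors,
)
from .metrics import confusion, performance

TRANSITIONS = {("A", "G"), ("T", "C"), ("C", "T"), ("G", "A")}


@dataclass
class NoiseProfile:
    """Ground-truth error structure of a simulated panel.

    ``rates`` maps (position, alt, strand) to the true per-read error rate;
    depths are drawn per strand as NegativeBinomial(mean=depth_mean,
    size=depth_dispersion), or held constant when ``depth_dispersion`` is
    None.
    """

    positions: list[PositionKey]
    rates: dict[tuple[PositionKey, str, str], float]
    depth_mean: float = 1000.0
    depth_dispersion: float | None = 20.0

    def rate(self, key: PositionKey, alt: str, strand: str) -> float:
        return self.rates[(key, alt, strand)]


def default_panel_positions(
    n_positions: int = 200, chrom: str = "chr1", start: int = 1000, seed: int = 0
) -> list[PositionKey]:
    """Consecutive panel positions with reference bases drawn uniformly."""
    rng = np.random.default_rng(seed)
    refs = rng.choice(list(BASES), size=n_positions)
    return [
        PositionKey(chrom, start + i, str(refs[i])) for i in range(n_positions)
    ]


def uniform_profile(
    positions: list[PositionKey],
    rate: float,
    depth_mean: float = 1000.0,
    depth_dispersion: float | None = None,
) -> NoiseProfile:
    """Identical true error rate everywhere; constant depth by default."""
    rates = {
        (key, alt, strand): rate
        for key in positions
        for alt in BASES
        if alt != key.ref
        for strand in "+-"
    }
    return NoiseProfile(positions, rates, depth_mean, depth_dispersion)


def heterogeneous_profile(
    positions: list[PositionKey],
    seed: int,
    median_rate: float = 3e-4,
    log_sigma: float = 1.0,
    transition_multiplier: float = 3.0,
    hot_fraction: float = 0.02,
    hot_multiplier: float = 20.0,
    max_rate: float = 0.045,
    depth_mean: float = 1000.0,
    depth_dispersion: float | None = 20.0,
) -> NoiseProfile:
    """Log-normal position/allele/strand-specific rates with transition bias.

    The defaults give a background centred near 3e-4 with a long right tail,
    transitions elevated ~3x, and ~2% of (position, allele) pairs "hot" at
    rates approaching 1%; rates are capped below the 5% germline/noise
    separation threshold so hot positions still register as noise.
    """
    rng = np.random.default_rng(seed)
    rates: dict[tuple[PositionKey, str, str], float] = {}
    for key in positions:
        for alt in BASES:
            if alt == key.ref:
                continue
            base = median_rate * float(np.exp(rng.normal(0.0, log_sigma)))
            if (key.ref, alt) in TRANSITIONS:
                base *= transition_multiplier
            if rng.random() < hot_fraction:
                base *= hot_multiplier
            for strand in "+-":
                jitter = float(np.exp(rng.normal(0.0, 0.2)))
                rates[(key, alt, strand)] = min(base * jitter, max_rate)
    return NoiseProfile(positions, rates, depth_mean, depth_dispersion)


@dataclass
class SimConfig:
    """Study design for the benchmark drivers.

    ``het_sites`` maps (position, alt) to the population carrier frequency of
    a germline heterozygous variant; carriers draw that allele at 50% VAF.
    The coverage/VAF/pseudo-count grids follow the synthetic-variant design:
    total depth COV in {800, 1600, 3200, 6400}, VAF in {0.5, 1, 1.25, 2, 3,
    4}% and C spanning 0.001-0.02.
    """

    n_normals: int = 60
    seed: int = 0
    het_sites: dict[tuple[PositionKey, str], float] = field(default_factory=dict)
    cov_grid: tuple[int, ...] = (800, 1600, 3200, 6400)
    vaf_grid: tuple[float, ...] = (0.005, 0.01, 0.0125, 0.02, 0.03, 0.04)
    pseudo_grid: tuple[float, ...] = (0.001, 0.002, 0.005, 0.01, 0.02)


def default_het_sites(
    positions: list[PositionKey],
    n_sites: int = 10,
    carrier_freq: float = 0.3,
    seed: int = 0,
) -> dict[tuple[PositionKey, str], float]:
    """Pick positions to carry a germline heterozygous variant.

    Carrier frequency below ~0.5 keeps the sites callable: the error model
    drops carrier samples via the 5% VAF filter, and only sites where >= 2/3
    of normals are dropped become non-callable.
    """
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(positions), size=min(n_sites, len(positions)), replace=False)
    sites: dict[tuple[PositionKey, str], float] = {}
    for idx in sorted(chosen):
        key = positions[int(idx)]
        alts = [b for b in BASES if b != key.ref]
        alt = alts[int(rng.integers(len(alts)))]
        sites[(key, alt)] = carrier_freq
    return sites


def _draw_depth(rng: np.random.Generator, mean: float, dispersion: float | None) -> int:
    if dispersion is None:
        return int(round(mean))
    # NB parameterised by size (shape) and success prob: mean = n(1-p)/p
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def simulate_normals(
    profile: NoiseProfile,
    n: int,
    seed: int,
    het_sites: dict[tuple[PositionKey, str], float] | None = None,
) -> list[SampleCounts]:
    """Simulate a cohort of n normal samples; fully determined by the seed."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    het_sites = het_sites or {}
    samples: list[SampleCounts] = []
    for i in range(n):
        records: dict[PositionKey, StrandCounts] = {}
        carried = {
            site for site, freq in het_sites.items() if rng.random() < freq
        }
        for key in profile.positions:
            depth_fwd = _draw_depth(rng, profile.depth_mean, profile.depth_dispersion)
            depth_rev = _draw_depth(rng, profile.depth_mean, profile.depth_dispersion)
            alt_fwd = {b: 0 for b in BASES}
            alt_rev = {b: 0 for b in BASES}
            for alt in BASES:
                if alt == key.ref:
                    continue
                if (key, alt) in carried:
                    e_fwd = e_rev = 0.5
                else:
                    e_fwd = profile.rate(key, alt, "+")
                    e_rev = profile.rate(key, alt, "-")
                alt_fwd[alt] = int(rng.binomial(depth_fwd, e_fwd)) if depth_fwd else 0
                alt_rev[alt] = int(rng.binomial(depth_rev, e_rev)) if depth_rev else 0
            for counts, depth in ((alt_fwd, depth_fwd), (alt_rev, depth_rev)):
                nonref = sum(counts[b] for b in BASES if b != key.ref)
                if nonref > depth:  # vanishingly rare; trim the largest draw
                    excess = nonref - depth
                    top = max(
                        (b for b in BASES if b != key.ref), key=lambda b: counts[b]
                    )
                    counts[top] -= excess
                    nonref = depth
                counts[key.ref] = depth - nonref
            records[key] = StrandCounts(depth_fwd, depth_rev, alt_fwd, alt_rev)
        samples.append(SampleCounts(sample_id=f"normal_{i:03d}", records=records))
    return samples


def make_synthetic_variant(
    cov_total: int,
    vaf: float,
    key: PositionKey | None = None,
    alt: str | None = None,
) -> ObservedAllele:
    """Spike-in allele at total depth COV: COV/2 reads per strand, a = COV*vaf/2
    supporting reads on each strand.

    The (COV, VAF) pair must give a whole number of supporting reads.
    """
    if cov_total <= 0 or cov_total % 2:
        raise ValueError(f"cov_total must be a positive even integer, got {cov_total}")
    a = cov_total * vaf / 2.0
    if abs(a - round(a)) > 1e-9:
        raise ValueError(
            f"COV={cov_total} with VAF={vaf} gives a non-integer supporting-read "
            f"count a={a}"
        )
    key = key or PositionKey("chr1", 1, "A")
    alt = alt or next(b for b in BASES if b != key.ref)
    a = int(round(a))
    half = cov_total // 2
    return ObservedAllele(key=key, alt=alt, k_fwd=a, k_rev=a, K_fwd=half, K_rev=half)


def run_synthetic_variant_experiment(
    models: ErrorModel | dict[float, ErrorModel],
    sim: SimConfig | None = None,
    config: CallerConfig | None = None,
) -> pd.DataFrame:
    """Spike every (callable position, alt) with each (COV, VAF) combination and
    measure PASS-call sensitivity.

    ``models`` maps pseudo-count C to the model trained with it (a bare model
    is treated as a single-entry map keyed by its configured C). Returns one
    row per (C, COV, VAF) with columns n_total, n_called, n_pass, tpr.
    """
    sim = sim or SimConfig()
    config = config or CallerConfig()
    if isinstance(models, ErrorModel):
        models = {models.config.pseudo_count: models}
    rows = []
    for c_value, model in models.items():
        entries = [
            (key, alt, e)
            for (key, alt), e in model.entries.items()
            if e.callable
        ]
        s_fwd = np.array([e.s_fwd for _, _, e in entries])
        s_rev = np.array([e.s_rev for _, _, e in entries])
        max_vaf = np.array([e.max_normal_vaf for _, _, e in entries])
        for cov in sim.cov_grid:
            half = cov // 2
            if half <= config.rd_min:
                continue
            for vaf in sim.vaf_grid:
                proto = make_synthetic_variant(cov, vaf)
                a = proto.k_fwd
                p_fwd = special.gammainc(a, half * s_fwd) if a else np.ones_like(s_fwd)
                p_rev = special.gammainc(a, half * s_rev) if a else np.ones_like(s_rev)
                q_fwd = -10.0 * np.log10(np.clip(p_fwd, 1e-320, 1.0))
                q_rev = -10.0 * np.log10(np.clip(p_rev, 1e-320, 1.0))
                reported = np.minimum(q_fwd, q_rev) >= config.q_report
                # symmetric spikes cannot show strand bias; remaining flags:
                low_q = np.minimum(q_fwd, q_rev) < config.q_lowq
                low_support = a < config.min_supporting
                high_noise = (a > config.min_supporting) & (vaf < max_vaf)
                passed = reported & ~low_q & ~low_support & ~high_noise
                n_total = len(entries)
                rows.append(
                    {
                        "C": c_value,
                        "cov": cov,
                        "vaf": vaf,
                        "n_total": n_total,
                        "n_called": int(reported.sum()),
                        "n_pass": int(passed.sum()),
                        "tpr": float(passed.sum() / n_total) if n_total else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def _classify_calls(
    held_out: list[SampleCounts],
    model: ErrorModel,
    caller_config: CallerConfig,
    truth_vaf: float,
    rd_min: int,
) -> dict[str, float]:
    """Call held-out samples and score against the VAF-threshold truth labels.

    Candidates are alleles with at least one supporting read at positions deep
    enough to be considered; positives are candidates with VAF >= truth_vaf.
    Calls are scored two ways: every reported call with Q >= 20 on both
    strands, and PASS-only calls.
    """
    truth: set[tuple[str, PositionKey, str]] = set()
    q20_calls: set[tuple[str, PositionKey, str]] = set()
    pass_calls: set[tuple[str, PositionKey, str]] = set()
    for sample in held_out:
        for key, sc in sample:
            if sc.depth_fwd <= rd_min or sc.depth_rev <= rd_min:
                continue
            for alt in BASES:
                if alt == key.ref:
                    continue
                if sc.alt_fwd.get(alt, 0) == 0 and sc.alt_rev.get(alt, 0) == 0:
                    continue
                if sc.vaf(alt) >= truth_vaf:
                    truth.add((sample.sample_id, key, alt))
        for call in call_variants(sample, model, caller_config):
            ident = (sample.sample_id, call.observed.key, call.observed.alt)
            if min(call.q_fwd, call.q_rev) >= caller_config.q_lowq:
                q20_calls.add(ident)
            if call.is_pass:
                pass_calls.add(ident)
    out: dict[str, float] = {}
    for label, calls in (("q20", q20_calls), ("pass", pass_calls)):
        perf = performance(confusion(calls, truth))
        out[f"fdr_{label}"] = perf.fdr if perf.fdr is not None else np.nan
        out[f"tpr_{label}"] = perf.tpr if perf.tpr is not None else np.nan
    return out


def run_self_consistency(
    normals: list[SampleCounts],
    m_grid: tuple[int, ...] = (20,),
    c_grid: tuple[float, ...] = (0.002,),
    repeats: int = 10,
    seed: int = 0,
    caller_config: CallerConfig | None = None,
    model_config: ErrorModelConfig | None = None,
    truth_vaf: float = 0.20,
    baseline: bool = False,
) -> pd.DataFrame:
    """Train-on-M / test-on-rest protocol over a cohort of normals.

    Per repeat: pick M normals at random, train the error model with
    pseudo-count c (or, with ``baseline=True``, skip estimation and use the
    constant-rate model s = c), call variants on the N-M held-out normals,
    and label candidate alleles with VAF >= 20% as positives. Returns one row
    per (M, c, repeat) with FDR and TPR computed both over Q>=20 calls and
    over PASS-only calls; summarise with :func:`self_consistency_medians`.
    """
    caller_config = caller_config or CallerConfig()
    model_config = model_config or ErrorModelConfig()
    n = len(normals)
    if max(m_grid) >= n:
        raise ValueError(f"every M must be < cohort size {n}, got {m_grid}")
    rows = []
    rng = np.random.default_rng(seed)
    for m in m_grid:
        for c in c_grid:
            cfg = replace(model_config, pseudo_count=c)
            for rep in range(repeats):
                train_idx = rng.choice(n, size=m, replace=False)
                train_set = set(int(i) for i in train_idx)
                train = [normals[i] for i in sorted(train_set)]
                held_out = [s for i, s in enumerate(normals) if i not in train_set]
                if baseline:
                    positions = {
                        key: None for s in normals for key in s.records
                    }
                    model = constant_error_model(positions, rate=c, config=cfg)
                else:
                    model = estimate_errors(train, cfg)
                scores = _classify_calls(
                    held_out, model, caller_config, truth_vaf, caller_config.rd_min
                )
                rows.append({"M": m, "c": c, "repeat": rep, **scores})
    return pd.DataFrame(rows)


def self_consistency_medians(per_repeat: pd.DataFrame) -> pd.DataFrame:
    """Median FDR/TPR per (M, c) across repeats."""
    cols = ["fdr_q20", "tpr_q20", "fdr_pass", "tpr_pass"]
    return (
        per_repeat.groupby(["M", "c"], as_index=False)[cols]
        .median()
        .rename(columns={c: f"median_{c}" for c in cols})
    )


def baseline_caller_run(
    normals: list[SampleCounts],
    c_grid: tuple[float, ...] = (0.002,),
    m_grid: tuple[int, ...] = (20,),
    repeats: int = 10,
    seed: int = 0,
    caller_config: CallerConfig | None = None,
    model_config: ErrorModelConfig | None = None,
) -> pd.DataFrame:
    """Self-consistency protocol with the constant-rate model s = c everywhere
    (no error estimation); the comparison arm for the trained model."""
    return run_self_consistency(
        normals,
        m_grid=m_grid,
        c_grid=c_grid,
        repeats=repeats,
        seed=seed,
        caller_config=caller_config,
        model_config=model_config,
        baseline=True,
    )
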