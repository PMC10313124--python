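"""Synthetic ground truth for calibration and pipeline validation.

This module plays the role of a track-structure simulation campaign: it emits
per-quality yield tables, per-track damage summaries and SDD files drawn from
a fully specified parameter set, so every calibration routine can be
validated by parameter recovery without any external data.

All default numbers here are SYNTHETIC.  They are chosen to be
order-of-magnitude plausible for protons and alpha particles between 2 and
200 keV/um (tens of strand breaks per track, DSB-site complexities of 2-15),
but they are not anyone's published calibration.

Two generation paths exist:

* ``make_yield_table(truth, noise_sigma, seed)`` — per-quality *expected*
  yields and Gamma (a, b) values, exact at ``noise_sigma=0`` and perturbed by
  multiplicative lognormal noise otherwise.  This is the input for the
  calibration-recovery tests.
* ``make_track_summaries`` / ``make_sdd_fixture`` — the stochastic per-track
  path with Poisson counts and sampled complexities, exercising the full
  record-level pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    GammaComplexityParams,
    MGMParameters,
    SaturatingYield,
    YieldModelParams,
    gamma_params_at,
    sample_complexities,
)
from .damage_metrics import TrackDamageSummary
from .generator import GENOME_BP, N_CHROMOSOMES, decompose_complexity
from .microdosimetry import YF_VALID_RANGE
from .sdd_io import DamageSiteRecord, SDDHeader, write_sdd


def default_truth_params() -> MGMParameters:
    """A fully specified synthetic parameter set (NOT a published calibration).

    Yields per track rise from a few lesions at 2 keV/um to ~100-200 at
    200 keV/um with indirect saturation; DSB-site complexity means rise from
    ~2.5 to ~5.
    """
    return MGMParameters(
        yields=YieldModelParams(
            sb=SaturatingYield(k_direct=0.8, N_max=90.0, a_sat=0.02),
            bd=SaturatingYield(k_direct=0.5, N_max=140.0, a_sat=0.015),
            ds_total=SaturatingYield(k_direct=0.35, N_max=60.0, a_sat=0.018),
            c1=0.08,
            c2=0.002,
        ),
        gamma=GammaComplexityParams(
            poly_a=(4.0, 0.01, -1.0e-5),
            poly_b=(1.6, -0.004, 8.0e-6),
        ),
        provenance={"source": "synthetic ground truth (mgm.synthetic)"},
    )


@dataclass
class GroundTruth:
    """Parameter set + study design for a synthetic calibration campaign."""

    mgm: MGMParameters = field(default_factory=default_truth_params)
    yF_grid: np.ndarray = field(
        default_factory=lambda: np.geomspace(*YF_VALID_RANGE, 15)
    )
    tracks_per_quality: int = 500
    noise_sigma: float = 0.0  # multiplicative lognormal sigma on mean yields
    seed: int = 0

    def __post_init__(self) -> None:
        self.yF_grid = np.asarray(self.yF_grid, dtype=float)
        if np.any(self.yF_grid <= 0):
            raise ValueError("yF grid must be positive")
        if self.tracks_per_quality < 1:
            raise ValueError("tracks_per_quality must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _noise(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    if sigma == 0:
        return np.ones(size)
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def make_yield_table(truth: GroundTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-quality expected yields and Gamma parameters, optionally noisy.

    Returns ``(yield_table, gamma_table)`` in the column layout
    :func:`mgm.fitting.calibrate` consumes.  With ``truth.noise_sigma == 0``
    the values are the exact model curves; otherwise each entry is multiplied
    by an independent lognormal factor with that sigma (unit mean).
    Deterministic given ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed)
    y = truth.yF_grid
    p = truth.mgm.yields
    n = len(y)
    cols = {
        "yF": y,
        "sb_direct": p.sb.direct(y),
        "sb_indirect": p.sb.indirect(y),
        "bd_direct": p.bd.direct(y),
        "bd_indirect": p.bd.indirect(y),
        "ds_direct": p.ds_total.direct(y),
        "ds_indirect": p.ds_total.indirect(y),
        "ds_with_dsb": p.n_ds_with_dsb(y),
    }
    for name in list(cols):
        if name != "yF":
            cols[name] = cols[name] * _noise(rng, truth.noise_sigma, n)
    a_vals = np.empty(n)
    b_vals = np.empty(n)
    for i, yF in enumerate(y):
        a_vals[i], b_vals[i] = gamma_params_at(yF, truth.mgm.gamma)
    a_vals = a_vals * _noise(rng, truth.noise_sigma, n)
    b_vals = b_vals * _noise(rng, truth.noise_sigma, n)
    return (
        pd.DataFrame(cols),
        pd.DataFrame({"yF": y, "a": a_vals, "b": b_vals}),
    )


def _split_counts(rng: np.random.Generator, mean_direct: float,
                  mean_indirect: float) -> tuple[int, int]:
    return int(rng.poisson(mean_direct)), int(rng.poisson(mean_indirect))


def make_track_summaries(
    truth: GroundTruth, quality_index: int
) -> list[TrackDamageSummary]:
    """Stochastic per-track summaries for one radiation quality.

    Per track: Poisson direct/indirect SB and BD counts around the model
    means (times a lognormal per-quality factor when ``noise_sigma > 0``),
    a Poisson number of DSB-containing sites with mean n_ds_with_dsb(yF),
    complexities from the discretized Gamma law, and Poisson extra non-DSB
    sites making up the total-DS yield.  Deterministic given ``truth.seed``.
    """
    yF = float(truth.yF_grid[quality_index])
    rng = np.random.default_rng(
        np.random.SeedSequence([truth.seed, quality_index])
    )
    p = truth.mgm.yields
    f = float(_noise(rng, truth.noise_sigma, 1)[0])
    mean_dsb_sites = p.n_ds_with_dsb(yF) * f
    mean_ds_total = p.ds_total.total(yF) * f
    mean_extra_ds = max(mean_ds_total - mean_dsb_sites, 0.0)
    out = []
    for track_id in range(truth.tracks_per_quality):
        sbd, sbi = _split_counts(rng, p.sb.direct(yF) * f, p.sb.indirect(yF) * f)
        bdd, bdi = _split_counts(rng, p.bd.direct(yF) * f, p.bd.indirect(yF) * f)
        n_dsb = int(rng.poisson(mean_dsb_sites))
        comps = sample_complexities(n_dsb, yF, truth.mgm.gamma, rng)
        n_extra = int(rng.poisson(mean_extra_ds))
        out.append(
            TrackDamageSummary(
                track_id=track_id,
                n_sb=sbd + sbi,
                n_bd=bdd + bdi,
                n_sb_direct=sbd,
                n_sb_indirect=sbi,
                n_bd_direct=bdd,
                n_bd_indirect=bdi,
                n_ds_total=n_dsb + n_extra,
                n_ds_with_dsb=n_dsb,
                complexities=[int(c) for c in comps],
            )
        )
    return out


def make_sdd_records(
    truth: GroundTruth, quality_index: int, n_tracks: int
) -> tuple[SDDHeader, list[DamageSiteRecord]]:
    """Site-level records for one quality: every DSB site carries a lesion
    pattern realizing its sampled complexity, plus non-DSB filler sites.

    Genomic positions are spaced on 20-bp slots so no two generated sites
    share a 10-bp window (accumulation tests perturb this deliberately).
    """
    yF = float(truth.yF_grid[quality_index])
    rng = np.random.default_rng(
        np.random.SeedSequence([truth.seed, quality_index, 1])
    )
    p = truth.mgm.yields
    nucleus_r = 9.65 / 2
    chrom_size = GENOME_BP // N_CHROMOSOMES
    n_slots = chrom_size // 20
    records = []
    for track_id in range(n_tracks):
        n_dsb = int(rng.poisson(p.n_ds_with_dsb(yF)))
        comps = sample_complexities(n_dsb, yF, truth.mgm.gamma, rng)
        n_extra = int(
            rng.poisson(max(p.ds_total.total(yF) - p.n_ds_with_dsb(yF), 0.0))
        )
        for k in range(n_dsb + n_extra):
            chrom = int(rng.integers(1, N_CHROMOSOMES + 1))
            pos = int(rng.integers(0, n_slots)) * 20
            xyz = tuple(float(v) for v in rng.uniform(-nucleus_r, nucleus_r, 3))
            if k < n_dsb:
                sb1, sb2, bd = decompose_complexity(int(comps[k]))
                has_dsb = True
            else:
                # non-DSB site: a single lesion, strand break or base damage
                if rng.uniform() < 0.5:
                    sb1, sb2, bd = 1, 0, 0
                else:
                    sb1, sb2, bd = 0, 0, 1
                has_dsb = False
            total = sb1 + sb2 + bd
            direct = int(rng.binomial(total, 0.6))
            records.append(
                DamageSiteRecord(
                    track_id=track_id,
                    chromosome_id=chrom,
                    genomic_position_bp=pos,
                    spatial_position_um=xyz,
                    n_sb_strand1=sb1,
                    n_sb_strand2=sb2,
                    n_bd=bd,
                    has_dsb=has_dsb,
                    cause_direct=direct,
                    cause_indirect=total - direct,
                )
            )
    header = SDDHeader(
        simulator_name="mgm-synthetic",
        dose_or_fluence=0.0,
        particle="synthetic",
        energy_MeV=0.0,
        site_definition_bp=10,
        free_fields={"Ground truth": "synthetic (mgm.synthetic)"},
    )
    return header, records


def make_sdd_fixture(
    truth: GroundTruth, quality_index: int, n_tracks: int, path: str | Path
) -> Path:
    """Write a synthetic SDD file for one quality; returns the path."""
    header, records = make_sdd_records(truth, quality_index, n_tracks)
    path = Path(path)
    write_sdd(header, records, path)
    return path
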