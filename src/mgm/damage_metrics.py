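"""Observables from raw damage records.

Turns per-site damage records into the quantities the model is calibrated on:
the integer complexity score of each DSB-containing site, per-track lesion
yields split by direct/indirect cause, cross-track damage accumulation at
shared genomic sites, bootstrapped per-Gy yields, and complexity histograms
with an RMSE distance between them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sdd_io import DamageSiteRecord, derive_has_dsb, group_by_track


def complexity_score(record: DamageSiteRecord) -> int | None:
    """Complexity of a damage site: total strand breaks plus base damages,
    defined only for sites containing at least one DSB.

    A simple DSB (one break on each strand, nothing else) scores 2 — the
    minimum.  Sites without a DSB have no complexity score and return None:
    they are excluded from the complexity distribution.
    """
    if not record.has_dsb:
        return None
    return record.n_sb_strand1 + record.n_sb_strand2 + record.n_bd


@dataclass
class TrackDamageSummary:
    """Per-track damage tally.

    Direct/indirect splits are site-level apportionments; when any record in
    the track lacks cause information, ``cause_split_available`` is False and
    the split fields hold only the attributable part.
    """

    track_id: int
    n_sb: int = 0
    n_bd: int = 0
    n_sb_direct: int = 0
    n_sb_indirect: int = 0
    n_bd_direct: int = 0
    n_bd_indirect: int = 0
    n_ds_total: int = 0
    n_ds_with_dsb: int = 0
    complexities: list[int] = field(default_factory=list)
    cause_split_available: bool = True


def _split_site_by_cause(r: DamageSiteRecord) -> tuple[int, int, int, int]:
    """Apportion a site's SB/BD counts to direct/indirect causes.

    The SDD site record carries only total direct and indirect lesion counts,
    not a per-lesion-type breakdown, so the cause ratio is applied to both
    lesion types proportionally (largest-remainder rounding on the SB side).
    """
    n_sb = r.n_sb_strand1 + r.n_sb_strand2
    total = n_sb + r.n_bd
    if not r.has_cause_info or total == 0:
        return 0, 0, 0, 0
    sb_direct = int(round(r.cause_direct * n_sb / total))
    sb_direct = min(sb_direct, n_sb, r.cause_direct)
    bd_direct = r.cause_direct - sb_direct
    if bd_direct > r.n_bd:  # rounding pushed too much onto BD
        sb_direct += bd_direct - r.n_bd
        bd_direct = r.n_bd
    return sb_direct, n_sb - sb_direct, bd_direct, r.n_bd - bd_direct


def summarize_tracks(
    records: Iterable[DamageSiteRecord] | Mapping[int, Sequence[DamageSiteRecord]],
) -> list[TrackDamageSummary]:
    """Collapse records into one :class:`TrackDamageSummary` per track.

    Accepts a flat record iterable (grouped internally, order-preserving) or a
    pre-grouped ``{track_id: records}`` mapping.  Complexities are collected
    only from DSB-containing sites.
    """
    if not isinstance(records, Mapping):
        records = group_by_track(records)
    out = []
    for track_id, recs in records.items():
        s = TrackDamageSummary(track_id=track_id)
        for r in recs:
            s.n_ds_total += 1
            s.n_sb += r.n_sb_strand1 + r.n_sb_strand2
            s.n_bd += r.n_bd
            sbd, sbi, bdd, bdi = _split_site_by_cause(r)
            if not r.has_cause_info and r.total_lesions > 0:
                s.cause_split_available = False
            s.n_sb_direct += sbd
            s.n_sb_indirect += sbi
            s.n_bd_direct += bdd
            s.n_bd_indirect += bdi
            c = complexity_score(r)
            if c is not None:
                s.n_ds_with_dsb += 1
                s.complexities.append(c)
        out.append(s)
    return out


def accumulate_tracks(
    records: Iterable[DamageSiteRecord], window_bp: int = 10
) -> list[DamageSiteRecord]:
    """Merge damage from independent tracks that hit overlapping sites.

    Sites on the same chromosome whose ``window_bp``-wide windows overlap are
    merged (transitively) by summing all lesion and cause counts; the merged
    site keeps the minimum start coordinate and the first contributing
    track's id, and ``has_dsb`` is re-derived from the summed strand breaks —
    this is how two single-strand breaks from different tracks combine into a
    double-strand break at high dose.
    """
    records = list(records)
    by_chrom: dict[int, list[DamageSiteRecord]] = {}
    for r in records:
        by_chrom.setdefault(r.chromosome_id, []).append(r)
    merged: list[DamageSiteRecord] = []
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda r: r.genomic_position_bp)
        cluster: list[DamageSiteRecord] = []
        cluster_end = -1
        for r in recs:
            if cluster and r.genomic_position_bp < cluster_end:
                cluster.append(r)
                cluster_end = max(cluster_end, r.genomic_position_bp + window_bp)
            else:
                if cluster:
                    merged.append(_merge_cluster(cluster))
                cluster = [r]
                cluster_end = r.genomic_position_bp + window_bp
        if cluster:
            merged.append(_merge_cluster(cluster))
    return merged


def _merge_cluster(cluster: list[DamageSiteRecord]) -> DamageSiteRecord:
    if len(cluster) == 1:
        return cluster[0]
    first = cluster[0]
    sb1 = sum(r.n_sb_strand1 for r in cluster)
    sb2 = sum(r.n_sb_strand2 for r in cluster)
    bd = sum(r.n_bd for r in cluster)
    have_cause = all(r.has_cause_info for r in cluster)
    return DamageSiteRecord(
        track_id=first.track_id,
        chromosome_id=first.chromosome_id,
        genomic_position_bp=first.genomic_position_bp,
        spatial_position_um=first.spatial_position_um,
        n_sb_strand1=sb1,
        n_sb_strand2=sb2,
        n_bd=bd,
        has_dsb=derive_has_dsb(sb1, sb2),
        cause_direct=sum(r.cause_direct for r in cluster) if have_cause else 0,
        cause_indirect=sum(r.cause_indirect for r in cluster) if have_cause else 0,
    )


#: Observables reported by :func:`bootstrap_yields`.
YIELD_OBSERVABLES = (
    "sb", "sb_direct", "sb_indirect",
    "bd", "bd_direct", "bd_indirect",
    "ds_total", "ds_with_dsb",
)


@dataclass(frozen=True)
class YieldEstimate:
    mean: float  # per Gy
    variance: float
    n_bootstrap: int
    dose_Gy: float

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be >= 0")
        if self.dose_Gy <= 0:
            raise ValueError("dose must be positive")


def bootstrap_yields(
    summaries: Sequence[TrackDamageSummary],
    dose_Gy: float,
    tracks_per_dose: int,
    n_bootstrap: int = 40,
    rng: np.random.Generator | int | None = None,
) -> dict[str, YieldEstimate]:
    """Bootstrap per-Gy damage yields by resampling whole tracks.

    Each of the ``n_bootstrap`` replicates draws ``tracks_per_dose`` tracks
    with replacement (the track is the resampling unit), sums each observable
    and divides by the nominal dose those tracks correspond to.  Returns the
    bootstrap mean and variance per observable; deterministic given ``rng``.
    """
    if not summaries:
        raise ValueError("no track summaries to bootstrap")
    if tracks_per_dose < 1 or n_bootstrap < 1:
        raise ValueError("tracks_per_dose and n_bootstrap must be >= 1")
    rng = np.random.default_rng(rng)
    table = np.array(
        [
            [s.n_sb, s.n_sb_direct, s.n_sb_indirect,
             s.n_bd, s.n_bd_direct, s.n_bd_indirect,
             s.n_ds_total, s.n_ds_with_dsb]
            for s in summaries
        ],
        dtype=float,
    )
    idx = rng.integers(0, len(summaries), size=(n_bootstrap, tracks_per_dose))
    per_rep = table[idx].sum(axis=1) / dose_Gy  # (n_bootstrap, n_observables)
    means = per_rep.mean(axis=0)
    variances = per_rep.var(axis=0)
    return {
        name: YieldEstimate(float(m), float(v), n_bootstrap, dose_Gy)
        for name, m, v in zip(YIELD_OBSERVABLES, means, variances)
    }


def complexity_histogram(
    complexities: Sequence[int] | np.ndarray, bin_width: int = 1
) -> pd.Series:
    """Normalized histogram of complexity scores on integer-aligned bins.

    Returns a Series indexed by bin start (bin covers [start, start+width));
    masses sum to one.
    """
    c = np.asarray(complexities)
    if c.size == 0:
        raise ValueError("no complexities to histogram")
    if np.any(c < 2):
        raise ValueError("complexity scores are >= 2 by definition")
    starts = (c // bin_width) * bin_width
    counts = pd.Series(starts).value_counts().sort_index()
    return counts / counts.sum()


def distribution_rmse(hist_a: pd.Series, hist_b: pd.Series) -> float:
    """Root mean square difference of two histograms' bin masses, computed on
    the union of their supports (missing bins count as zero mass)."""
    grid = hist_a.index.union(hist_b.index)
    a = hist_a.reindex(grid, fill_value=0.0).to_numpy(dtype=float)
    b = hist_b.reindex(grid, fill_value=0.0).to_numpy(dtype=float)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def summaries_to_frame(summaries: Sequence[TrackDamageSummary]) -> pd.DataFrame:
    """Tabular view of track summaries for CSV export (complexities joined
    with '|')."""
    return pd.DataFrame(
        {
            "track_id": [s.track_id for s in summaries],
            "n_sb": [s.n_sb for s in summaries],
            "n_sb_direct": [s.n_sb_direct for s in summaries],
            "n_sb_indirect": [s.n_sb_indirect for s in summaries],
            "n_bd": [s.n_bd for s in summaries],
            "n_bd_direct": [s.n_bd_direct for s in summaries],
            "n_bd_indirect": [s.n_bd_indirect for s in summaries],
            "n_ds_total": [s.n_ds_total for s in summaries],
            "n_ds_with_dsb": [s.n_ds_with_dsb for s in summaries],
            "complexities": ["|".join(map(str, s.complexities)) for s in summaries],
        }
    )
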