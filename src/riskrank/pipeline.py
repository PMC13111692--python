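"""End-to-end analysis pipeline: chunking, fitting, filtering, assembly.

The per-individual trial stream is segmented into consecutive 1500-trial
chunks; each chunk is fitted by maximum likelihood; degenerate and outlier
fits are filtered (side-bias guard, then pooled IQR fences on the five PT
parameters); individuals left with fewer than 10 chunks are excluded; and
the survivors are merged with the concurrent hierarchy measures (mean Elo,
COP) and individual metadata into the per-chunk analysis table consumed by
the mixed models.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import hierarchy, pt_fitting
from .hierarchy import EloConfig
from .pt_fitting import PT_PARAMS, ChunkFit, FitConfig

__all__ = [
    "chunk_trials",
    "iter_chunks",
    "fit_all_chunks",
    "side_bias",
    "iqr_filter",
    "exclude_individuals",
    "age_category",
    "assemble_table",
    "run_pipeline",
    "FilterReport",
    "PipelineResult",
]

log = logging.getLogger(__name__)

DEFAULT_CHUNK_SIZE = 1500
MIN_CHUNKS = 10


def chunk_trials(trials: pd.DataFrame, size: int = DEFAULT_CHUNK_SIZE) -> pd.DataFrame:
    """Assign consecutive non-overlapping chunk indices per individual.

    Returns a copy with a ``chunk_index`` column; the trailing remainder
    shorter than ``size`` is dropped.  Individuals with fewer than ``size``
    trials contribute no chunks (logged).
    """
    if size < 1:
        raise ValueError("chunk size must be >= 1")
    out = []
    for ind, sub in trials.groupby("individual_id", sort=False):
        sub = sub.sort_values("trial_index", kind="stable")
        n_chunks = len(sub) // size
        if n_chunks == 0:
            log.info("individual %s has %d < %d trials: no chunks", ind, len(sub), size)
            continue
        kept = sub.iloc[: n_chunks * size].copy()
        kept["chunk_index"] = np.arange(len(kept)) // size
        out.append(kept)
    if not out:
        return trials.iloc[0:0].assign(chunk_index=pd.Series(dtype=int))
    return pd.concat(out, ignore_index=True)


def iter_chunks(chunked: pd.DataFrame):
    for (ind, ci), sub in chunked.groupby(["individual_id", "chunk_index"], sort=True):
        yield ind, int(ci), sub


def fit_all_chunks(
    chunked: pd.DataFrame, config: FitConfig = FitConfig()
) -> List[ChunkFit]:
    return [
        pt_fitting.fit_chunk(sub, config, chunk_index=ci)
        for _, ci, sub in iter_chunks(chunked)
    ]


def side_bias(records) -> float:
    """max(fraction left, fraction right) of the recorded choices."""
    choice = np.asarray(records["choice"])
    if len(choice) == 0:
        raise ValueError("side_bias of empty record list")
    fr = float(np.mean(choice == "right"))
    return max(fr, 1.0 - fr)


@dataclass
class FilterReport:
    """Bookkeeping of the filtering stage (counts reconcile with inputs)."""

    fences: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    quantile_method: str = "linear"
    n_chunks_in: int = 0
    n_removed_side_bias: int = 0
    n_removed_iqr: int = 0
    removed: List[Tuple[str, int, str]] = field(default_factory=list)
    excluded_individuals: List[dict] = field(default_factory=list)
    trials_discarded_fraction: float = 0.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def iqr_filter(
    fits: pd.DataFrame,
    params: Sequence[str] = PT_PARAMS,
    whisker: float = 1.5,
    report: Optional[FilterReport] = None,
    fences: Optional[Dict[str, Tuple[float, float]]] = None,
) -> Tuple[pd.DataFrame, FilterReport]:
    """Remove chunks with any PT parameter outside the pooled IQR fences.

    Fences are Q1 - 1.5*IQR / Q3 + 1.5*IQR computed per parameter on the
    pooled distribution across all individuals' chunks (linear-interpolation
    quantiles).  The chunk is the unit of removal: one out-of-fence
    parameter removes the whole row.  Passing ``fences`` reuses frozen
    fences instead of recomputing them.
    """
    if fences is None and len(fits) < 4:
        raise ValueError("need at least 4 pooled chunks to compute IQR fences")
    report = report or FilterReport()
    report.n_chunks_in = report.n_chunks_in or len(fits)
    if fences is None:
        fences = {}
        for p in params:
            vals = fits[p].to_numpy(dtype=float)
            q1, q3 = np.percentile(vals, [25, 75])  # linear interpolation
            iqr = q3 - q1
            if iqr == 0:
                log.warning("degenerate IQR=0 for %s; fences collapse to quartiles", p)
            fences[p] = (q1 - whisker * iqr, q3 + whisker * iqr)
    report.fences = {p: (float(lo), float(hi)) for p, (lo, hi) in fences.items()}

    keep = np.ones(len(fits), dtype=bool)
    for p in params:
        lo, hi = fences[p]
        vals = fits[p].to_numpy(dtype=float)
        keep &= (vals >= lo) & (vals <= hi)
    removed = fits.loc[~keep]
    for r in removed.itertuples(index=False):
        report.removed.append((str(r.individual_id), int(r.chunk_index), "iqr"))
    report.n_removed_iqr += int((~keep).sum())
    return fits.loc[keep].reset_index(drop=True), report


def exclude_individuals(
    retained: pd.DataFrame,
    min_chunks: int = MIN_CHUNKS,
    report: Optional[FilterReport] = None,
) -> Tuple[pd.DataFrame, FilterReport]:
    """Drop individuals with fewer than ``min_chunks`` retained chunks.

    "Fewer than" is strict: an individual with exactly ``min_chunks`` chunks
    is retained.  The report records mean side bias separately for excluded
    and retained individuals (the excluded group is typically far more
    one-sided).
    """
    report = report or FilterReport()
    counts = retained.groupby("individual_id").size()
    keep_ids = set(counts[counts >= min_chunks].index)
    drop_ids = set(counts.index) - keep_ids
    for ind in sorted(map(str, drop_ids)):
        sub = retained[retained["individual_id"] == ind]
        report.excluded_individuals.append(
            {
                "individual_id": ind,
                "reason": f"fewer than {min_chunks} retained chunks",
                "n_retained": int(len(sub)),
                "mean_side_bias": float(sub["side_bias"].mean())
                if "side_bias" in sub.columns
                else float("nan"),
            }
        )
    out = retained[retained["individual_id"].isin(keep_ids)].reset_index(drop=True)
    if len(out) == 0:
        raise ValueError("no individuals left after exclusion")
    return out, report


def age_category(age_years: float, sex: str) -> str:
    """Age class at the evaluation date.

    Juveniles are under 4 years; subadults 4-8 (males) or 4-7 (females);
    adults above.  Boundaries are half-open: a male turning exactly 8 is an
    adult.
    """
    if age_years < 0:
        raise ValueError("age must be non-negative")
    if age_years < 4:
        return "juvenile"
    adult_at = 8 if str(sex).lower().startswith("m") else 7
    return "subadult" if age_years < adult_at else "adult"


def _zscore(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return x * 0.0
    return (x - x.mean()) / sd


def assemble_table(
    fits: pd.DataFrame,
    hier: pd.DataFrame,
    metadata: pd.DataFrame,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> pd.DataFrame:
    """Merge fits, hierarchy measures and metadata into the analysis table.

    Inner join on (individual, chunk); chunks with no hierarchy coverage are
    dropped (logged).  Adds natural-log transforms of lam/alpha, the age
    category at each chunk's midpoint date, the experience covariate (mean
    cumulative trial index of the chunk) and z-scored copies of Elo and
    experience computed on the assembled table.
    """
    merged = fits.merge(hier, on=["individual_id", "chunk_index"], how="inner")
    n_orphan = len(fits) - len(merged)
    if n_orphan:
        log.info("dropped %d chunks with no hierarchy overlap", n_orphan)
    merged = merged[np.isfinite(merged["elo_mean"])].reset_index(drop=True)

    meta = metadata.set_index(metadata["individual_id"].astype(str))
    merged["sex"] = merged["individual_id"].astype(str).map(meta["sex"])
    birth = pd.to_datetime(meta["birth_date"])
    mid = (
        pd.to_datetime(merged["t_start"])
        + (pd.to_datetime(merged["t_end"]) - pd.to_datetime(merged["t_start"])) / 2
    )
    age_years = (
        mid - merged["individual_id"].astype(str).map(birth)
    ).dt.days / 365.25
    merged["age_years"] = age_years
    merged["age_category"] = [
        age_category(a, s) for a, s in zip(merged["age_years"], merged["sex"])
    ]

    merged["log_lam"] = np.log(merged["lam"])
    merged["log_alpha_plus"] = np.log(merged["alpha_plus"])
    merged["log_alpha_minus"] = np.log(merged["alpha_minus"])
    merged["experience"] = merged["chunk_index"] * chunk_size + (chunk_size - 1) / 2
    merged["elo_z"] = _zscore(merged["elo_mean"])
    merged["experience_z"] = _zscore(merged["experience"])
    return merged


@dataclass
class PipelineResult:
    table: pd.DataFrame
    chunk_fits: pd.DataFrame
    filter_report: FilterReport
    elo: hierarchy.EloTrajectory
    manifest: dict

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "analysis_table.csv", index=False)
        self.chunk_fits.to_csv(out / "chunk_fits.csv", index=False)
        self.elo.to_long().to_csv(out / "elo_trajectory.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def run_pipeline(
    trials: pd.DataFrame,
    events: pd.DataFrame,
    metadata: pd.DataFrame,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    fit_config: Optional[FitConfig] = None,
    elo_config: Optional[EloConfig] = None,
    min_chunks: int = MIN_CHUNKS,
    side_bias_threshold: float = 0.95,
) -> PipelineResult:
    """Run the full analysis from raw logs to the per-chunk table.

    Deterministic given the input logs and the fit seed.  Side-bias-flagged
    chunks are removed before the IQR fences are computed so degenerate fits
    cannot distort them.
    """
    fit_config = fit_config or FitConfig()
    elo_config = elo_config or EloConfig()

    chunked = chunk_trials(trials, chunk_size)
    total_chunked = len(chunked)
    fits = pt_fitting.fits_to_frame(fit_all_chunks(chunked, fit_config))
    if len(fits) == 0:
        raise ValueError("no individual reached a full chunk of trials")

    report = FilterReport(n_chunks_in=len(fits))
    biased = fits["side_bias"] >= side_bias_threshold
    for r in fits.loc[biased].itertuples(index=False):
        report.removed.append((str(r.individual_id), int(r.chunk_index), "side_bias"))
    report.n_removed_side_bias = int(biased.sum())
    fits_ok = fits.loc[~biased].reset_index(drop=True)

    retained, report = iqr_filter(fits_ok, report=report)
    retained, report = exclude_individuals(retained, min_chunks, report)
    report.trials_discarded_fraction = (
        1.0 - len(retained) * chunk_size / total_chunked if total_chunked else 0.0
    )

    roster = metadata["individual_id"].astype(str).tolist()
    traj = hierarchy.compute_elo(events, roster, elo_config)
    spans = retained[["individual_id", "chunk_index", "t_start", "t_end"]]
    hier = hierarchy.align_hierarchy_to_chunks(traj, events, spans)
    table = assemble_table(retained, hier, metadata, chunk_size)

    manifest = {
        "chunk_size": chunk_size,
        "min_chunks": min_chunks,
        "side_bias_threshold": side_bias_threshold,
        "fit_config": {
            "bounds": fit_config.bounds,
            "n_multistart": fit_config.n_multistart,
            "seed": fit_config.seed,
        },
        "elo_config": dataclasses.asdict(elo_config),
        "filter_report": report.to_dict(),
        "n_rows": int(len(table)),
        "n_individuals": int(table["individual_id"].nunique()),
    }
    return PipelineResult(table, fits, report, traj, manifest)
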