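"""Biomarker evaluation: ROC/AUC with percentile-bootstrap confidence
intervals, Spearman association with continuous TMB, Kaplan-Meier survival
stratification with the log-rank test, and patch-probability heatmaps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    tpr: np.ndarray  # sensitivity
    fpr: np.ndarray  # 1 - specificity
    auc: float


def roc_auc(scores, labels) -> ROCCurve:
    """ROC curve and trapezoidal AUC.  The AUC equals the fraction of
    (positive, negative) pairs ordered correctly, ties counted 1/2."""
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present for ROC analysis")
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thr, tpr=tpr, fpr=fpr, auc=auc)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapCI:
    point_estimate: float
    lower: float
    upper: float
    level: float
    n_replicates: int
    seed: int
    n_redrawn: int = 0


def bootstrap_ci(
    data,
    statistic,
    n_replicates: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
    max_redraws: int = 1000,
) -> BootstrapCI:
    """Percentile bootstrap interval for ``statistic(rows of data)``.

    The resampling unit is the row (one patient: score and label jointly).
    Interval endpoints are nearest-rank order statistics of the replicate
    vector: with B replicates and tail mass a = (1 - level)/2, the lower
    endpoint is replicate number ceil(a*B) and the upper replicate number
    ceil((1-a)*B) (1-based).  Replicates on which the statistic is
    undefined (raises or returns NaN) are redrawn, and the count logged.
    """
    arr = np.asarray(data)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations to bootstrap")
    rng = np.random.default_rng(seed)
    point = float(statistic(arr))

    reps = np.empty(n_replicates)
    n_redrawn = 0
    for b in range(n_replicates):
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            try:
                val = float(statistic(arr[idx]))
            except Exception:
                val = float("nan")
            if np.isfinite(val):
                reps[b] = val
                break
            n_redrawn += 1
        else:
            raise RuntimeError("statistic undefined on too many resamples")
    if n_redrawn:
        logger.info("bootstrap redrew %d degenerate resamples", n_redrawn)

    reps.sort()
    a = (1.0 - level) / 2.0
    k_lo = max(int(np.ceil(a * n_replicates)), 1) - 1
    k_hi = min(int(np.ceil((1.0 - a) * n_replicates)), n_replicates) - 1
    return BootstrapCI(
        point_estimate=point,
        lower=float(reps[k_lo]),
        upper=float(reps[k_hi]),
        level=level,
        n_replicates=n_replicates,
        seed=seed,
        n_redrawn=n_redrawn,
    )


# ---------------------------------------------------------------------------
# rank correlation
# ---------------------------------------------------------------------------


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson on mid-ranks; average ranks for
    ties)."""
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length vectors of size >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("zero rank variance: correlation undefined")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


@dataclass
class SurvivalRecord:
    patient_id: str
    time: float  # days
    event: int  # 1 = event observed, 0 = censored
    group: str  # "high" or "low" by the stored PITER cutoff

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be > 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def km_estimate(records: list[SurvivalRecord]) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit survival curve per group.

    Returns {group: frame(time, survival)} with right-continuous step values
    at the distinct event times (censored subjects leave the risk set after
    their time)."""
    from lifelines import KaplanMeierFitter

    if not records:
        raise ValueError("no survival records")
    df = pd.DataFrame(
        [{"time": r.time, "event": r.event, "group": r.group} for r in records]
    )
    out = {}
    for g, sub in df.groupby("group"):
        if sub.empty:
            raise ValueError(f"empty survival group {g}")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        sf = kmf.survival_function_
        out[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return out


def logrank_test(records: list[SurvivalRecord]) -> tuple[float, float]:
    """Two-group log-rank test (observed minus expected over event times,
    1 df).  Returns (chi-square statistic, p-value)."""
    from lifelines.statistics import logrank_test as _lr

    df = pd.DataFrame(
        [{"time": r.time, "event": r.event, "group": r.group} for r in records]
    )
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError("log-rank test needs exactly two groups")
    if df["event"].sum() == 0:
        raise ValueError("no events observed; log-rank test undefined")
    a = df[df["group"] == groups[0]]
    b = df[df["group"] == groups[1]]
    res = _lr(a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# heatmap
# ---------------------------------------------------------------------------


def render_heatmap(
    predictions: pd.DataFrame,
    slide_dims: tuple[int, int],
    patch_px: int,
    out_png: str | None = None,
) -> np.ndarray:
    """Grid of TMB-high probabilities for one slide.

    Cell (row, col) = (y // patch_px, x // patch_px) holds p_tmb_high; cells
    without a patch are NaN (missing).  Rendered with the viridis map, so
    high-probability regions appear yellow/warm.  Overlapping patches at one
    cell are averaged with a warning.
    """
    w, h = slide_dims
    n_cols = int(np.ceil(w / patch_px))
    n_rows = int(np.ceil(h / patch_px))
    grid = np.full((n_rows, n_cols), np.nan)
    counts = np.zeros((n_rows, n_cols), dtype=int)
    sums = np.zeros((n_rows, n_cols))
    for _, row in predictions.iterrows():
        x, y = int(row["x"]), int(row["y"])
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(f"patch at ({x}, {y}) outside slide bounds {slide_dims}")
        r, c = y // patch_px, x // patch_px
        sums[r, c] += float(row["p_tmb_high"])
        counts[r, c] += 1
    if (counts > 1).any():
        warnings.warn("overlapping patches in heatmap cell(s); values averaged")
    nz = counts > 0
    grid[nz] = sums[nz] / counts[nz]

    if out_png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 6 * n_rows / max(n_cols, 1)))
        im = ax.imshow(grid, cmap="viridis", vmin=0.0, vmax=1.0)
        ax.set_title("TMB-high probability")
        fig.colorbar(im, ax=ax, shrink=0.8)
        fig.savefig(out_png, dpi=120)
        plt.close(fig)
    return grid


def heatmap_to_csv(grid: np.ndarray, path) -> None:
    rows = []
    for r in range(grid.shape[0]):
        for c in range(grid.shape[1]):
            v = grid[r, c]
            rows.append({"row": r, "col": c, "value": "" if np.isnan(v) else v})
    pd.DataFrame(rows).to_csv(path, index=False)


def heatmap_from_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    n_rows, n_cols = df["row"].max() + 1, df["col"].max() + 1
    grid = np.full((n_rows, n_cols), np.nan)
    for _, row in df.iterrows():
        if row["value"] == "" or pd.isna(row["value"]):
            continue
        grid[int(row["row"]), int(row["col"])] = float(row["value"])
    return grid


# ---------------------------------------------------------------------------
# cohort report
# ---------------------------------------------------------------------------


def evaluate_cohort(
    scores: pd.DataFrame,
    manifest: pd.DataFrame,
    cutoff: float | None = None,
    n_bootstrap: int = 10_000,
    seed: int = 0,
) -> dict:
    """Bundle the biomarker evaluation into one report.

    ``scores`` needs columns patient_id, piter_score; labels and continuous
    TMB come from the manifest (tmb_class, tmb_value).  If survival columns
    are present and a cutoff is given, Kaplan-Meier curves and a log-rank
    test by PITER group are included.
    """
    for col in ("tmb_class", "tmb_value"):
        if col not in manifest.columns:
            raise ValueError(f"manifest missing label column: {col}")
    per_patient = manifest.drop_duplicates("patient_id")[
        [c for c in manifest.columns if c != "slide_id"]
    ]
    df = scores.merge(per_patient, on="patient_id", how="inner")
    if df.empty:
        raise ValueError("no overlap between scores and manifest patients")
    labels = (df["tmb_class"] == "high").astype(int).to_numpy()
    s = df["piter_score"].to_numpy(dtype=float)

    roc = roc_auc(s, labels)
    pairs = np.column_stack([s, labels])
    ci = bootstrap_ci(
        pairs,
        lambda a: roc_auc(a[:, 0], a[:, 1]).auc,
        n_replicates=n_bootstrap,
        seed=seed,
    )
    rho = spearman_rho(s, df["tmb_value"].to_numpy(dtype=float))

    report = {
        "n_patients": int(len(df)),
        "auc": roc.auc,
        "auc_ci_low": ci.lower,
        "auc_ci_high": ci.upper,
        "rho": rho,
    }

    if cutoff is not None:
        called_high = s >= cutoff
        n_pos = max(int(labels.sum()), 1)
        n_neg = max(int((1 - labels).sum()), 1)
        report["cutoff"] = float(cutoff)
        report["sensitivity"] = float((called_high & (labels == 1)).sum() / n_pos)
        report["specificity"] = float((~called_high & (labels == 0)).sum() / n_neg)

        has_surv = (
            "surv_time_days" in df.columns
            and "surv_event" in df.columns
            and pd.to_numeric(df["surv_time_days"], errors="coerce").notna().any()
        )
        if has_surv:
            records = []
            for i, (_, row) in enumerate(df.iterrows()):
                t = pd.to_numeric(pd.Series([row["surv_time_days"]]), errors="coerce").iloc[0]
                e = pd.to_numeric(pd.Series([row["surv_event"]]), errors="coerce").iloc[0]
                if pd.isna(t) or pd.isna(e):
                    continue
                records.append(
                    SurvivalRecord(
                        patient_id=row["patient_id"],
                        time=float(t),
                        event=int(e),
                        group="high" if called_high[i] else "low",
                    )
                )
            if records and len({r.group for r in records}) == 2:
                chi2, p = logrank_test(records)
                report["logrank_chi2"] = chi2
                report["logrank_p"] = p
                report["km"] = km_estimate(records)
    return report
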