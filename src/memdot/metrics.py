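"""Validation metrics for surface DOT reconstructions.

Four complementary metrics compare a reconstructed cortical map against a
known generator (ground-truth vertex set and time course):

* **AUC** — area under the ROC curve of the normalized absolute amplitudes
  at the evaluation time, truth vertices vs the rest of the field of view;
* **Dmin** — geodesic distance (mm) from the reconstruction peak to the
  border of the ground-truth region (0 when the peak falls inside it);
* **SD** — spatial dispersion: energy-weighted RMS geodesic distance (mm)
  to the truth region, penalizing both spread and mislocalization;
* **SE** — shape error: RMS difference between the max-normalized
  reconstructed and true time courses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra
from scipy.stats import wilcoxon
from sklearn.metrics import roc_curve, auc as sk_auc

from .mesh import CorticalMesh, geodesic_distance

__all__ = [
    "CorticalMap",
    "MetricsReport",
    "metric_auc",
    "metric_dmin",
    "metric_sd",
    "metric_se",
    "evaluate_trial",
    "aggregate",
]


@dataclass
class CorticalMap:
    """Reconstruction (or ground truth) amplitudes on a mesh over time."""

    amplitudes: np.ndarray        # vertices x time
    times: np.ndarray             # seconds
    method_tag: str
    mesh: CorticalMesh

    def peak_time_index(self) -> int:
        """Time sample of maximal spatial energy."""
        return int(np.argmax(np.sum(self.amplitudes**2, axis=0)))


@dataclass
class MetricsReport:
    auc: float
    dmin_mm: float
    sd_mm: float
    se: float
    method_tag: str = ""
    trial_ref: dict = field(default_factory=dict)


def _eval_index(recon: CorticalMap, eval_time: float | None) -> int:
    if eval_time is None:
        return recon.peak_time_index()
    return int(np.argmin(np.abs(recon.times - eval_time)))


def metric_auc(
    recon: CorticalMap,
    truth: np.ndarray,
    eval_time: float | None = None,
    fov_mask: np.ndarray | None = None,
) -> float:
    """ROC area of |amplitude| at the evaluation time over in-FOV vertices."""
    truth = np.asarray(truth, dtype=int)
    n = recon.amplitudes.shape[0]
    if truth.size == 0 or truth.size >= n:
        raise ValueError("truth set must be nonempty and a strict subset of vertices")
    ti = _eval_index(recon, eval_time)
    scores = np.abs(recon.amplitudes[:, ti])
    labels = np.zeros(n, dtype=int)
    labels[truth] = 1
    if fov_mask is not None:
        keep = np.asarray(fov_mask, dtype=bool) | (labels == 1)
        scores, labels = scores[keep], labels[keep]
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ValueError("degenerate truth/FOV combination")
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(sk_auc(fpr, tpr))


def truth_border(mesh: CorticalMesh, truth: np.ndarray) -> np.ndarray:
    """Truth vertices adjacent to at least one non-truth vertex."""
    truth_set = set(int(v) for v in truth)
    border = [v for v in truth_set if any(int(u) not in truth_set for u in mesh.neighbors[v])]
    return np.array(sorted(border), dtype=int)


def metric_dmin(
    recon: CorticalMap,
    truth: np.ndarray,
    mesh: CorticalMesh | None = None,
    eval_time: float | None = None,
) -> float:
    """Geodesic distance (mm) from the reconstruction peak to the truth border.

    Zero when the peak vertex lies inside the ground-truth region.  Ties in
    the peak amplitude resolve to the lowest vertex index.
    """
    mesh = mesh or recon.mesh
    truth = np.asarray(truth, dtype=int)
    ti = _eval_index(recon, eval_time)
    peak = int(np.argmax(np.abs(recon.amplitudes[:, ti])))
    if peak in set(int(v) for v in truth):
        return 0.0
    border = truth_border(mesh, truth)
    if border.size == 0:
        border = truth
    return float(np.min(geodesic_distance(mesh, peak, border)))


def metric_sd(
    recon: CorticalMap,
    truth: np.ndarray,
    mesh: CorticalMesh | None = None,
    eval_time: float | None = None,
    fov_mask: np.ndarray | None = None,
) -> float:
    """Energy-weighted RMS geodesic distance (mm) to the truth region.

    d(v) = 0 inside the truth, else the minimum geodesic distance from v to
    any truth vertex; SD = sqrt(sum d^2 x^2 / sum x^2) at the evaluation
    time over in-FOV vertices.
    """
    mesh = mesh or recon.mesh
    truth = np.asarray(truth, dtype=int)
    ti = _eval_index(recon, eval_time)
    x = np.abs(recon.amplitudes[:, ti]).astype(float)
    if fov_mask is not None:
        x = x * np.asarray(fov_mask, dtype=bool)
    if np.all(x == 0):
        raise ValueError("all-zero map: spatial dispersion undefined")
    d = dijkstra(mesh.graph, directed=False, indices=truth, min_only=True)
    d = np.asarray(d)
    d[truth] = 0.0
    w = x**2
    finite = np.isfinite(d)
    return float(np.sqrt(np.sum(d[finite] ** 2 * w[finite]) / np.sum(w[finite])))


def metric_se(recon_tc: np.ndarray, truth_tc: np.ndarray) -> float:
    """Shape error: RMS difference of max-abs-normalized time courses."""
    r = np.asarray(recon_tc, dtype=float)
    t = np.asarray(truth_tc, dtype=float)
    if r.shape != t.shape:
        raise ValueError("time courses must have equal length")
    rm, tm = np.abs(r).max(), np.abs(t).max()
    if rm == 0 or tm == 0:
        raise ValueError("zero time course: shape error undefined")
    diff = r / rm - t / tm
    return float(np.sqrt(np.mean(diff**2)))


def region_time_course(recon: CorticalMap, region: np.ndarray, eval_time: float | None = None) -> np.ndarray:
    """Energy-weighted mean time course over a vertex region.

    Weights are the squared amplitudes at the evaluation time, so the
    course tracks the vertices actually reconstructed as active.
    """
    region = np.asarray(region, dtype=int)
    ti = _eval_index(recon, eval_time)
    w = recon.amplitudes[region, ti] ** 2
    if w.sum() == 0:
        w = np.ones_like(w)
    return (recon.amplitudes[region, :].T @ w) / w.sum()


def evaluate_trial(
    recon: CorticalMap,
    truth_vertices: np.ndarray,
    truth_tc: np.ndarray,
    mesh: CorticalMesh | None = None,
    fov_mask: np.ndarray | None = None,
    trial_ref: dict | None = None,
    eval_time: float | None = None,
) -> MetricsReport:
    """All four metrics for one reconstruction against its ground truth.

    ``eval_time`` fixes the map evaluation sample (e.g. the response peak);
    by default the sample of maximal spatial energy is used.
    """
    mesh = mesh or recon.mesh
    recon_tc = region_time_course(recon, truth_vertices, eval_time=eval_time)
    return MetricsReport(
        auc=metric_auc(recon, truth_vertices, eval_time=eval_time, fov_mask=fov_mask),
        dmin_mm=metric_dmin(recon, truth_vertices, mesh, eval_time=eval_time),
        sd_mm=metric_sd(recon, truth_vertices, mesh, eval_time=eval_time, fov_mask=fov_mask),
        se=metric_se(recon_tc, truth_tc),
        method_tag=recon.method_tag,
        trial_ref=dict(trial_ref or {}),
    )


def reports_to_frame(reports) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {"method": r.method_tag, "auc": r.auc, "dmin_mm": r.dmin_mm, "sd_mm": r.sd_mm, "se": r.se}
        row.update(r.trial_ref)
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate(reports, group_by=(), paired: bool = True) -> pd.DataFrame:
    """Median/quartile summary per method (and grouping cell), with paired
    method differences and Wilcoxon signed-rank p-values (Bonferroni).

    ``reports`` is a list of :class:`MetricsReport` or a long DataFrame with
    columns method/auc/dmin_mm/sd_mm/se plus grouping factors.
    """
    df = reports if isinstance(reports, pd.DataFrame) else reports_to_frame(reports)
    if df.empty:
        raise ValueError("no reports to aggregate")
    metrics = ["auc", "dmin_mm", "sd_mm", "se"]
    keys = list(group_by)
    group_cols = keys + ["method"]
    summary = (
        df.groupby(group_cols)[metrics]
        .quantile([0.25, 0.5, 0.75])
        .unstack(-1)
    )
    summary.columns = [f"{m}_q{int(q*100)}" for m, q in summary.columns]
    summary = summary.reset_index()

    if not paired or df["method"].nunique() < 2:
        return summary

    methods = sorted(df["method"].unique())
    n_tests = len(metrics) * len(methods) * (len(methods) - 1) // 2
    rows = []
    grouped = df.groupby(keys) if keys else [((), df)]
    for cell, sub in grouped:
        for i, m1 in enumerate(methods):
            for m2 in methods[i + 1 :]:
                a = sub[sub["method"] == m1].sort_values("trial") if "trial" in sub else sub[sub["method"] == m1]
                b = sub[sub["method"] == m2].sort_values("trial") if "trial" in sub else sub[sub["method"] == m2]
                if len(a) != len(b):
                    raise ValueError(f"mismatched trial sets for paired comparison {m1} vs {m2}")
                for met in metrics:
                    diff = a[met].to_numpy() - b[met].to_numpy()
                    if np.allclose(diff, 0):
                        p = 1.0
                    else:
                        p = float(wilcoxon(diff, zero_method="wilcox").pvalue)
                    rows.append(
                        {
                            **({k: v for k, v in zip(keys, cell if isinstance(cell, tuple) else (cell,))}),
                            "comparison": f"{m1} - {m2}",
                            "metric": met,
                            "median_diff": float(np.median(diff)),
                            "p_bonferroni": min(1.0, p * n_tests),
                        }
                    )
    pairs = pd.DataFrame(rows)
    summary.attrs["paired"] = pairs
    return summary
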