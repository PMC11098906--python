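"""Lesion-level evaluation of spread-out views.

A *lesion* is a maximal run of consecutive frames whose plaque burden
(fraction of the cross-section occupied by plaque) is at least 40%.
Metrics are computed per lesion by restricting the binarized predicted
and ground-truth spread-out views to the lesion's frame columns and
treating the 360 x length grid as a confusion matrix: accuracy is
(TP + TN) / all elements, F1 is 2TP / (2TP + FP + FN).  Pixel-domain
overlap metrics (IoU, Dice, Hausdorff) do not apply because the angular
labels carry no pixel-level extent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .spreadout import SpreadOutView

MIN_PLAQUE_BURDEN = 0.40


@dataclass(frozen=True)
class Lesion:
    """A contiguous high-burden vessel segment."""

    vessel_id: str
    frame_range: tuple[int, int]  # half-open
    plaque_burden: float

    def __post_init__(self) -> None:
        lo, hi = self.frame_range
        if hi <= lo:
            raise ValueError("lesion frame_range must be nonempty")
        if self.plaque_burden < MIN_PLAQUE_BURDEN:
            raise ValueError(
                f"included lesions require plaque burden >= {MIN_PLAQUE_BURDEN}, got {self.plaque_burden}"
            )


@dataclass
class MetricsResult:
    """Per-lesion metric table plus per-class/method summaries."""

    table: pd.DataFrame  # lesion_id, class, method, accuracy, f1
    summary: pd.DataFrame  # class, method, metric, median, mean

    def format_median_mean(self) -> str:
        """Render summaries in the conventional ``median (mean)`` layout."""
        lines = []
        for _, row in self.summary.iterrows():
            lines.append(
                f"{row['method']:>20s}  {row['class']:>10s}  {row['metric']:>8s}  "
                f"{row['median']:.2f} ({row['mean']:.2f})"
            )
        return "\n".join(lines)


def extract_lesions(
    burden_per_frame: np.ndarray,
    min_burden: float = MIN_PLAQUE_BURDEN,
    min_len_frames: int = 1,
    vessel_id: str = "vessel",
) -> list[Lesion]:
    """Maximal runs of frames with burden >= ``min_burden`` and length >=
    ``min_len_frames``; each run's burden is its frame mean."""
    b = np.asarray(burden_per_frame, dtype=float)
    above = b >= min_burden
    lesions: list[Lesion] = []
    start = None
    for i, flag in enumerate(np.append(above, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_len_frames:
                lesions.append(Lesion(vessel_id, (start, i), float(b[start:i].mean())))
            start = None
    return lesions


def lesion_metrics(
    pred: SpreadOutView, gt: SpreadOutView, lesion: Lesion
) -> tuple[float, float]:
    """(accuracy, F1) of a binarized prediction against ground truth over
    one lesion's frame columns.

    Empty-ground-truth convention: with no positive ground-truth element
    in the lesion, F1 is 1.0 when the prediction is also empty and 0.0
    otherwise (accuracy stays well defined either way).
    """
    if pred.values.shape != gt.values.shape:
        raise ValueError("prediction and ground truth views must share shape")
    lo, hi = lesion.frame_range
    if not (0 <= lo < hi <= pred.n_frames):
        raise ValueError(f"lesion range {lesion.frame_range} outside view with {pred.n_frames} frames")
    p = pred.values[:, lo:hi] > 0.5
    g = gt.values[:, lo:hi] > 0.5
    tp = int((p & g).sum())
    tn = int((~p & ~g).sum())
    fp = int((p & ~g).sum())
    fn = int((~p & g).sum())
    accuracy = (tp + tn) / p.size
    if tp + fp + fn == 0:
        f1 = 1.0
    else:
        f1 = 2 * tp / (2 * tp + fp + fn)
    return float(accuracy), float(f1)


def evaluate_lesions(
    preds: dict[str, SpreadOutView],
    gts: dict[str, SpreadOutView],
    lesions: list[Lesion],
    method: str = "model",
) -> pd.DataFrame:
    """Per-lesion per-class metric rows for one prediction method."""
    rows = []
    for i, lesion in enumerate(lesions):
        for cls, pred in preds.items():
            acc, f1 = lesion_metrics(pred, gts[cls], lesion)
            rows.append(
                {"lesion_id": i, "class": cls, "method": method, "accuracy": acc, "f1": f1}
            )
    return pd.DataFrame(rows, columns=["lesion_id", "class", "method", "accuracy", "f1"])


def summarize(
    table: pd.DataFrame, figure_path: str | Path | None = None
) -> MetricsResult:
    """Median and mean per class, method and metric, with an optional
    violin + box figure (one violin per method per class)."""
    if table.empty:
        raise ValueError("no lesions to summarize")
    rows = []
    for (cls, method), grp in table.groupby(["class", "method"]):
        for metric in ("accuracy", "f1"):
            vals = grp[metric].to_numpy()
            rows.append(
                {
                    "class": cls,
                    "method": method,
                    "metric": metric,
                    "median": float(np.median(vals)),
                    "mean": float(np.mean(vals)),
                }
            )
    summary = pd.DataFrame(rows, columns=["class", "method", "metric", "median", "mean"])
    if figure_path is not None:
        _violin_figure(table, Path(figure_path))
    return MetricsResult(table=table, summary=summary)


def _violin_figure(table: pd.DataFrame, path: Path) -> None:
    classes = sorted(table["class"].unique())
    metrics = ("accuracy", "f1")
    fig, axes = plt.subplots(len(metrics), len(classes), figsize=(4 * len(classes), 6), squeeze=False)
    for mi, metric in enumerate(metrics):
        for ci, cls in enumerate(classes):
            ax = axes[mi][ci]
            sub = table[table["class"] == cls]
            methods = sorted(sub["method"].unique())
            data = [sub[sub["method"] == m][metric].to_numpy() for m in methods]
            # KDE degenerates when every lesion scores identically; the
            # box plot alone still shows the distribution then.
            spread = [d for d in data if len(d) > 1 and np.ptp(d) > 0]
            if len(spread) == len(data):
                parts = ax.violinplot(data, showextrema=False)
                for pc in parts["bodies"]:
                    pc.set_alpha(0.5)
            ax.boxplot(data, widths=0.15)
            ax.set_xticks(range(1, len(methods) + 1), methods, rotation=20)
            ax.set_ylim(-0.05, 1.05)
            ax.set_title(f"{cls} {metric}")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
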