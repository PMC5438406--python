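"""Exhaustive descriptor-subset search with ranked report tables.

Evaluates every non-empty subset of the 14 descriptors (16383 masks for
the full set) with a *shared* split list — the same random train/test
draws for every subset — so the subset ranking is not confounded by
split-sampling noise.  Produces, in the format of the study's report
tables: the top-k subsets ranked by pooled AUC with per-descriptor
inclusion flags, the per-descriptor presence counts over the top k, and
the seven predefined subsets (all image descriptors / volumes /
morphology, each with and without gestational age, plus GA alone) with
their ROC curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .classify import CvDesign, SubsetResult, evaluate, precompute_design
from .features import (
    CohortTable,
    DESCRIPTORS,
    MORPHOLOGY_DESCRIPTORS,
    VOLUME_DESCRIPTORS,
)

__all__ = [
    "SubsetMask",
    "SearchReport",
    "enumerate_subsets",
    "predefined_subsets",
    "run_search",
    "write_report",
]


@dataclass(frozen=True)
class SubsetMask:
    """Inclusion flags over the 14 canonical descriptors.

    ``value`` is the binary encoding (bit j set = descriptor j of
    :data:`~neomorph.features.DESCRIPTORS` included); used as the
    deterministic tie-break in rankings.
    """

    flags: tuple[bool, ...]

    def __post_init__(self) -> None:
        if not any(self.flags):
            raise ValueError("subset mask must include at least one descriptor")

    @property
    def value(self) -> int:
        return sum(1 << j for j, f in enumerate(self.flags) if f)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(d for d, f in zip(DESCRIPTORS, self.flags) if f)

    @classmethod
    def from_names(cls, names: Sequence[str]) -> "SubsetMask":
        unknown = [n for n in names if n not in DESCRIPTORS]
        if unknown:
            raise ValueError(f"unknown descriptors: {unknown}")
        s = set(names)
        return cls(flags=tuple(d in s for d in DESCRIPTORS))

    @classmethod
    def from_value(cls, value: int, n: int = len(DESCRIPTORS)) -> "SubsetMask":
        return cls(flags=tuple(bool(value >> j & 1) for j in range(n)))

    def as_array(self) -> np.ndarray:
        return np.array(self.flags, dtype=np.bool_)


def enumerate_subsets(n_descriptors: int = len(DESCRIPTORS)) -> list[SubsetMask]:
    """All 2^n - 1 non-empty subsets in binary-counter order."""
    if not 1 <= n_descriptors <= 20:
        raise ValueError("n_descriptors must be in 1..20")
    return [SubsetMask.from_value(v, n_descriptors) for v in range(1, 2**n_descriptors)]


def predefined_subsets() -> dict[str, SubsetMask]:
    """The seven fixed subsets evaluated alongside the full search."""
    image = [d for d in DESCRIPTORS if d != "GA"]
    return {
        "GA_only": SubsetMask.from_names(["GA"]),
        "all_image": SubsetMask.from_names(image),
        "all_image_with_GA": SubsetMask.from_names(["GA", *image]),
        "volumes": SubsetMask.from_names(list(VOLUME_DESCRIPTORS)),
        "volumes_with_GA": SubsetMask.from_names(["GA", *VOLUME_DESCRIPTORS]),
        "morphology": SubsetMask.from_names(list(MORPHOLOGY_DESCRIPTORS)),
        "morphology_with_GA": SubsetMask.from_names(["GA", *MORPHOLOGY_DESCRIPTORS]),
    }


@dataclass
class SearchReport:
    """Outcome of a full subset search on one cohort table.

    ``ranked`` has one row per evaluated subset, sorted by pooled AUC
    descending (ties broken by mask binary value), with columns ``auc``,
    ``mask_value`` and one boolean column per descriptor.
    """

    ranked: pd.DataFrame
    presence_counts: pd.Series
    predefined: dict[str, SubsetResult]
    design: CvDesign
    outcome: str
    k: int
    n_skipped: int

    @property
    def top(self) -> pd.DataFrame:
        return self.ranked.head(self.k)

    @property
    def best(self) -> pd.Series:
        return self.ranked.iloc[0]


def run_search(
    table: CohortTable,
    design: CvDesign,
    outcome: str = "cognitive",
    k: int = 10,
    C: float = 1.0,
    masks: Sequence[SubsetMask] | None = None,
) -> SearchReport:
    """Exhaustively evaluate descriptor subsets on shared splits.

    Every mask (default: all 16383) is scored by pooled AUC over the same
    split list; the seven predefined subsets are evaluated on those
    splits as well (they are members of the enumeration, so the best
    full-search AUC can never fall below the best predefined AUC).
    """
    if masks is None:
        masks = enumerate_subsets(len(DESCRIPTORS))
    if any(len(m.flags) != len(DESCRIPTORS) for m in masks):
        raise ValueError("subset masks must cover all 14 canonical descriptors")
    X, y = table.features(), table.labels(outcome)
    pre = precompute_design(X, y, design)
    mask_arr = np.stack([m.as_array() for m in masks])
    aucs = _kernels.search_masks_auc(
        pre.Xtr, pre.ytr, pre.Xte, pre.yte, pre.fold_id, pre.fallback, mask_arr, C
    )

    frame = pd.DataFrame({"auc": aucs, "mask_value": [m.value for m in masks]})
    for j, d in enumerate(DESCRIPTORS):
        frame[d] = mask_arr[:, j]
    ranked = frame.sort_values(
        ["auc", "mask_value"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)

    top = ranked.head(k)
    presence = pd.Series(
        {d: int(top[d].sum()) for d in DESCRIPTORS}, name="presence_count"
    )

    predefined = {
        name: evaluate(table, mask.names, design, outcome=outcome, C=C, _pre=pre)
        for name, mask in predefined_subsets().items()
    }
    return SearchReport(
        ranked=ranked,
        presence_counts=presence,
        predefined=predefined,
        design=design,
        outcome=outcome,
        k=k,
        n_skipped=pre.n_skipped,
    )


def _flag_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Render boolean descriptor columns as 'x'/'' report flags."""
    out = df.copy()
    for d in DESCRIPTORS:
        out[d] = np.where(out[d], "x", "")
    return out


def write_report(report: SearchReport, outdir: str | Path,
                 plot: bool = True) -> dict[str, Path]:
    """Persist a search report: ranked CSV, presence counts, ROCs, figure.

    The ranked CSV mirrors the report-table layout (AUC followed by one
    flag column per descriptor in canonical order).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ranked_path = outdir / "ranked_subsets.csv"
    _flag_frame(report.ranked).to_csv(ranked_path, index=False, float_format="%.6f")
    paths["ranked"] = ranked_path

    top_path = outdir / f"top_{report.k}_subsets.csv"
    _flag_frame(report.top).to_csv(top_path, index=False, float_format="%.6f")
    paths["top"] = top_path

    counts_path = outdir / "presence_counts.csv"
    report.presence_counts.rename_axis("descriptor").to_csv(counts_path)
    paths["presence_counts"] = counts_path

    for name, res in report.predefined.items():
        p = outdir / f"roc_{name}.csv"
        pd.DataFrame(
            {"fpr": res.roc.fpr, "tpr": res.roc.tpr, "threshold": res.roc.thresholds}
        ).to_csv(p, index=False)
        paths[f"roc_{name}"] = p

    summary = pd.DataFrame(
        [
            {"subset": name, "pooled_auc": res.pooled_auc, "n_skipped": res.n_skipped}
            for name, res in report.predefined.items()
        ]
    )
    summary_path = outdir / "predefined_subsets.csv"
    summary.to_csv(summary_path, index=False, float_format="%.6f")
    paths["predefined"] = summary_path

    if plot:
        paths["figure"] = _plot_rocs(report, outdir / "roc_curves.png")
    return paths


def _plot_rocs(report: SearchReport, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 5))
    for name, res in report.predefined.items():
        ax.plot(res.roc.fpr, res.roc.tpr, lw=1.2,
                label=f"{name} (AUC {res.pooled_auc:.2f})")
    best_auc = float(report.best["auc"])
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="chance")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(
        f"{report.outcome} outcome, pooled ROC "
        f"(best subset AUC {best_auc:.2f})"
    )
    ax.legend(fontsize=7, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
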