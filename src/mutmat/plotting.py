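"""Bar-chart visualization of mutational matrices.

One bar per channel in matrix-file order, grouped and colored by
substitution class or indel family; the per-sample portrait lays out the ten
plottable classifications on a single page.  Colors follow the conventional
six-color substitution palette with analogous families for doublets and
indels; exact hues are an aesthetic choice.
"""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

SBS_PALETTE = {
    "C>A": "#03BCEE", "C>G": "#010101", "C>T": "#E32926",
    "T>A": "#CAC9C9", "T>C": "#A1CE63", "T>G": "#EBC6C4",
}
_FAMILY_CYCLE = (
    "#03BCEE", "#010101", "#E32926", "#CAC9C9", "#A1CE63", "#EBC6C4",
    "#E6A5C8", "#6058A4", "#F6C56B", "#4C9A2A", "#A85C32", "#7F7F7F",
)

PLOTTABLE = (
    "SBS6", "SBS24", "SBS96", "SBS384", "SBS1536",
    "DBS78", "DBS186", "ID28", "ID83", "ID415",
)


def _strip_strand(label: str) -> str:
    head = label.split(":", 1)[0]
    return label.split(":", 1)[1] if head in ("T", "U", "B", "N", "Q") else label


def channel_group(scheme: str, label: str) -> str:
    """The color-group of one channel: substitution class for SBS, reference
    doublet for DBS, (length class, kind, subtype) family for indels."""
    core = _strip_strand(label)
    if scheme.startswith("SBS"):
        if "[" in core:
            core = core[core.index("[") + 1 : core.index("]")]
        return core
    if scheme.startswith("DBS"):
        return core.split(">")[0]
    parts = core.split(":")
    if len(parts) >= 3 and parts[0] in ("Del", "Ins"):  # ID-28 labels
        return f"{parts[0]}:{parts[1]}"
    return ":".join(parts[:3])


def _colors(scheme: str, labels) -> list[str]:
    groups = [channel_group(scheme, lbl) for lbl in labels]
    if scheme.startswith("SBS"):
        return [SBS_PALETTE.get(g, "#7F7F7F") for g in groups]
    palette = {}
    for g in groups:
        palette.setdefault(g, _FAMILY_CYCLE[len(palette) % len(_FAMILY_CYCLE)])
    return [palette[g] for g in groups]


def _draw(ax, matrix: pd.DataFrame, scheme: str, sample: str, percentage: bool):
    values = matrix[sample].to_numpy(dtype=float)
    if percentage:
        total = values.sum()
        values = 100.0 * values / total if total > 0 else values
    labels = list(matrix.index)
    ax.bar(range(len(labels)), values, color=_colors(scheme, labels), width=0.7)
    ax.set_xlim(-1, len(labels))
    ax.set_ylabel("%" if percentage else "count", fontsize=7)
    ax.set_title(f"{scheme} — {sample}", fontsize=8)
    if len(labels) <= 96:
        ax.set_xticks(range(len(labels)))
        ax.set_xticklabels(labels, rotation=90, fontsize=3)
    else:
        ax.set_xticks([])
    ax.tick_params(axis="y", labelsize=6)
    return len(labels)


def plot_matrix(
    matrix: pd.DataFrame,
    scheme: str,
    sample: str,
    out_path: str | Path,
    percentage: bool = False,
) -> Path:
    """Render one scheme × sample spectrum as a bar chart (PDF/PNG by
    extension).  ``scheme`` must be one of the plottable classifications."""
    if scheme not in PLOTTABLE:
        raise ValueError(f"scheme {scheme!r} is not plottable; choose from {PLOTTABLE}")
    if sample not in matrix.columns:
        raise KeyError(
            f"unknown sample {sample!r}; available: {list(matrix.columns)}"
        )
    fig, ax = plt.subplots(figsize=(max(4, len(matrix) / 12), 2.5))
    _draw(ax, matrix, scheme, sample, percentage)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path)
    plt.close(fig)
    return out_path


def plot_portrait(
    matrices: dict[str, pd.DataFrame],
    sample: str,
    out_path: str | Path,
    percentage: bool = False,
) -> Path:
    """All ten plottable classifications for one sample on a single page."""
    missing = [s for s in PLOTTABLE if s not in matrices]
    if missing:
        raise KeyError(f"portrait requires all ten schemes; missing: {missing}")
    fig, axes = plt.subplots(5, 2, figsize=(14, 12))
    for ax, scheme in zip(axes.ravel(), PLOTTABLE):
        if sample not in matrices[scheme].columns:
            raise KeyError(
                f"unknown sample {sample!r}; available: "
                f"{list(matrices[scheme].columns)}"
            )
        _draw(ax, matrices[scheme], scheme, sample, percentage)
    fig.suptitle(sample)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path)
    plt.close(fig)
    return out_path
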