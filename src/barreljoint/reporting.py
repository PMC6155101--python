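"""Tabular and graphical output of pattern statistics.

One TSV per statistic plus a single JSON report, and (optionally) bar
charts and histograms.  Output is deterministic: identical inputs give
byte-identical TSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .patterns import PatternSummary

__all__ = ["write_pattern_report", "plot_pattern_report"]


def _counts_frame(
    groups: Mapping[str, PatternSummary], attr: str
) -> pd.DataFrame:
    rows = []
    for label, summary in groups.items():
        counts = getattr(summary, attr)
        for pattern, count in counts.items():
            key = pattern if isinstance(pattern, str) else "|".join(pattern)
            rows.append({"group": label, "pattern": key, "count": count})
    return pd.DataFrame(rows, columns=["group", "pattern", "count"])


def write_pattern_report(
    groups: Mapping[str, PatternSummary],
    position_table: pd.DataFrame,
    out_dir: str | Path,
    bin_width: float = 10.0,
) -> Path:
    """Write all statistic tables and the JSON mirror; returns out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stats = {
        "dyads_beta": "dyad_counts_beta",
        "dyads_gamma": "dyad_counts_gamma",
        "triads_beta": "triad_counts_beta",
        "triads_gamma": "triad_counts_gamma",
        "quadrant_dyads_gamma": "quadrant_dyad_counts_gamma",
    }
    for name, attr in stats.items():
        _counts_frame(groups, attr).to_csv(
            out / f"{name}.tsv", sep="\t", index=False
        )

    hist_rows = []
    for label, summary in groups.items():
        for kind in ("beta", "gamma"):
            h = getattr(summary, f"{kind}_histogram")(bin_width)
            for lo, hi, c in zip(h.edges[:-1], h.edges[1:], h.counts):
                hist_rows.append(
                    {
                        "group": label,
                        "angle_type": kind,
                        "bin_start": lo,
                        "bin_end": hi,
                        "count": int(c),
                    }
                )
    pd.DataFrame(
        hist_rows,
        columns=["group", "angle_type", "bin_start", "bin_end", "count"],
    ).to_csv(out / "histograms.tsv", sep="\t", index=False)

    position_table.to_csv(
        out / "positions.tsv", sep="\t", index=False, float_format="%.6f"
    )

    report = {
        label: {
            "n_structures": s.n_structures,
            "beta_signs": s.beta_signs,
            "gamma_signs": s.gamma_signs,
            "dyads_beta": s.dyad_counts_beta,
            "dyads_gamma": s.dyad_counts_gamma,
            "triads_beta": s.triad_counts_beta,
            "triads_gamma": s.triad_counts_gamma,
            "quadrant_dyads_gamma": {
                "|".join(k): v for k, v in s.quadrant_dyad_counts_gamma.items()
            },
        }
        for label, s in groups.items()
    }
    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return out


def plot_pattern_report(
    groups: Mapping[str, PatternSummary],
    out_dir: str | Path,
    bin_width: float = 10.0,
) -> None:
    """Bar charts of the dyad/triad tables and per-type angle histograms."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    for attr, title in (
        ("dyad_counts_beta", "beta dyads"),
        ("dyad_counts_gamma", "gamma dyads"),
        ("triad_counts_beta", "beta triads"),
        ("triad_counts_gamma", "gamma triads"),
    ):
        fig, ax = plt.subplots(figsize=(7, 4))
        frame = _counts_frame(groups, attr)
        if not frame.empty:
            pivot = frame.pivot(index="pattern", columns="group", values="count")
            pivot.plot.bar(ax=ax)
        ax.set_title(title)
        ax.set_ylabel("count")
        fig.tight_layout()
        fig.savefig(out / f"{attr}.png", dpi=120)
        plt.close(fig)

    for kind in ("beta", "gamma"):
        fig, ax = plt.subplots(figsize=(7, 4))
        for label, summary in groups.items():
            h = getattr(summary, f"{kind}_histogram")(bin_width)
            centers = (h.edges[:-1] + h.edges[1:]) / 2.0
            ax.step(centers, h.counts, where="mid", label=label)
        ax.set_xlabel(f"{kind} angle (degrees)")
        ax.set_ylabel("count")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / f"histogram_{kind}.png", dpi=120)
        plt.close(fig)
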