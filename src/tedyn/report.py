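"""Summary-report rendering.

Aggregates stage outputs into one machine-readable bundle: per-genome age
histograms, age-by-orthology-category splits, fixed/polymorphic counts and
age distributions, cluster statistics, the deletion size-class table and
the SV-TE association table.  The report layer only aggregates — every
number is recomputable from the stage TSVs it consumes.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .dating import DatingConfig, InsertionAge, age_histogram


def _hist_block(ages: list[InsertionAge], cfg: DatingConfig, recent_mya: float = 5.0) -> dict:
    df = age_histogram(ages, cfg, recent_mya=recent_mya)
    return {
        "bins": df.to_dict(orient="records"),
        "n_dated": df.attrs["n_dated"],
        "recent_mya": df.attrs["recent_mya"],
        "recent_count": df.attrs["recent_count"],
        "recent_fraction": df.attrs["recent_fraction"],
        "n_saturated": sum(1 for a in ages if a.status == "saturated"),
        "n_too_short": sum(1 for a in ages if a.status == "too_short"),
    }


def render_report(
    ages_by_genome: dict[str, list[InsertionAge]] | None = None,
    ortho_reports: dict[str, dict] | None = None,
    polymorphism: dict | None = None,
    cluster_report: dict | None = None,
    size_class_table: dict | None = None,
    sv_summary: dict | None = None,
    dating_cfg: DatingConfig | None = None,
    recent_mya: float = 5.0,
) -> dict:
    """Assemble the report bundle; every section is optional and omitted
    sections yield an empty-but-valid report."""
    dating_cfg = dating_cfg or DatingConfig()
    report: dict = {}
    if ages_by_genome is not None:
        report["age_histograms"] = {
            g: _hist_block(ages, dating_cfg, recent_mya) for g, ages in ages_by_genome.items()
        }
    if ortho_reports is not None:
        report["orthologous_insertions"] = ortho_reports
    if polymorphism is not None:
        report["polymorphism"] = polymorphism
    if cluster_report is not None:
        report["clusters"] = cluster_report
    if size_class_table is not None:
        report["deletion_size_classes"] = size_class_table
    if sv_summary is not None:
        report["structural_variants"] = sv_summary
    return report


def polymorphism_block(
    statuses, ages_mya: dict[str, float] | None = None, split_mya: float | None = None
) -> dict:
    """Fixed/polymorphic counts, and the age distribution of each group."""
    n_poly = sum(1 for s in statuses if s.status == "polymorphic")
    block: dict = {
        "n_insertions": len(statuses),
        "n_fixed": len(statuses) - n_poly,
        "n_polymorphic": n_poly,
        "fraction_polymorphic": n_poly / len(statuses) if statuses else None,
    }
    if ages_mya:
        for group in ("fixed", "polymorphic"):
            ages = [
                ages_mya[s.element_id]
                for s in statuses
                if s.status == group and s.element_id in ages_mya
            ]
            entry: dict = {"n_dated": len(ages)}
            if ages:
                entry["min_mya"] = min(ages)
                entry["max_mya"] = max(ages)
                if split_mya is not None:
                    entry["n_older_than_split"] = sum(1 for a in ages if a >= split_mya)
            block[f"{group}_ages"] = entry
    return block


def write_report(report: dict, outdir: str | Path, plots: bool = False) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "report.json"
    path.write_text(json.dumps(report, indent=2, default=_jsonable))
    if plots:
        _write_plots(report, outdir)
    return path


def _jsonable(obj):
    if isinstance(obj, (pd.Series,)):
        return obj.to_dict()
    if hasattr(obj, "item"):
        return obj.item()
    return str(obj)


def _write_plots(report: dict, outdir: Path) -> None:
    """Age-histogram plot per genome (optional; needs matplotlib)."""
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return
    hists = report.get("age_histograms")
    if not hists:
        return
    fig, ax = plt.subplots(figsize=(7, 4))
    for genome, block in hists.items():
        bins = block["bins"]
        if not bins:
            continue
        ax.bar(
            [b["bin_start_mya"] for b in bins],
            [b["count"] for b in bins],
            width=0.9 * (bins[0]["bin_end_mya"] - bins[0]["bin_start_mya"]),
            alpha=0.5,
            align="edge",
            label=genome,
        )
    ax.set_xlabel("insertion age (Mya)")
    ax.set_ylabel("elements")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "age_histograms.png", dpi=120)
    plt.close(fig)
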