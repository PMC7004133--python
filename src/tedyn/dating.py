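"""Insertion-age estimation from LTR-pair divergence.

The two LTRs of a retrotransposon are identical at insertion and diverge
independently afterwards, so the K2P distance K between them accrues on
both copies: E[K] = 2·r·T for a substitution rate r (per site per year).
The insertion age is therefore T = K / (2r), reported in Mya.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import K2PResult, SaturationError, global_align, k2p_distance
from .annotation import LTRElement


@dataclass(frozen=True)
class DatingConfig:
    """Parameters of the molecular-clock dating.

    substitution_rate: r, substitutions per site per year (default 1e-8,
    the canonical plant neutral rate used for Prunus).  generation_time is
    carried as metadata only — the rate is per year, so generations do not
    enter the formula.  min_sites: LTR pairs with fewer gap-free compared
    columns are flagged ``too_short`` (at 50 sites the binomial noise floor
    on K is already ~14%).
    """

    substitution_rate: float = 1e-8
    generation_time: float = 10.0
    bin_width_mya: float = 1.0
    min_sites: int = 50

    def __post_init__(self) -> None:
        if self.substitution_rate <= 0:
            raise ValueError("substitution_rate must be positive")


@dataclass
class InsertionAge:
    element_id: str
    k2p: K2PResult | None
    age_mya: float | None
    status: str  # dated | saturated | too_short


def age_from_k(k: float, cfg: DatingConfig) -> float:
    """T = K/(2r), in Mya."""
    return k / (2.0 * cfg.substitution_rate) / 1e6


def date_element(
    element: LTRElement, genome: dict[str, str], cfg: DatingConfig | None = None
) -> InsertionAge:
    """Date one element from the global alignment of its two LTRs."""
    cfg = cfg or DatingConfig()
    ltr5, ltr3 = element.ltr_sequences(genome)
    aln = global_align(ltr5, ltr3, query_id=f"{element.element_id}_ltr5",
                       target_id=f"{element.element_id}_ltr3")
    try:
        k2p = k2p_distance(aln)
    except SaturationError:
        return InsertionAge(element.element_id, None, None, "saturated")
    if k2p.compared_sites < cfg.min_sites:
        return InsertionAge(element.element_id, k2p, None, "too_short")
    return InsertionAge(element.element_id, k2p, age_from_k(k2p.K, cfg), "dated")


def date_elements(
    elements: list[LTRElement], genome: dict[str, str], cfg: DatingConfig | None = None
) -> list[InsertionAge]:
    cfg = cfg or DatingConfig()
    return [date_element(el, genome, cfg) for el in elements]


def ages_to_frame(ages: list[InsertionAge]) -> pd.DataFrame:
    rows = []
    for a in ages:
        rows.append(
            {
                "element_id": a.element_id,
                "P": a.k2p.P if a.k2p else float("nan"),
                "Q": a.k2p.Q if a.k2p else float("nan"),
                "K": a.k2p.K if a.k2p else float("nan"),
                "compared_sites": a.k2p.compared_sites if a.k2p else 0,
                "age_mya": a.age_mya if a.age_mya is not None else float("nan"),
                "status": a.status,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["element_id", "P", "Q", "K", "compared_sites", "age_mya", "status"],
    )


def age_histogram(
    ages: list[InsertionAge], cfg: DatingConfig | None = None, recent_mya: float = 5.0
) -> pd.DataFrame:
    """Bin dated ages into [i·w, (i+1)·w) Mya bins.

    Returns a frame with bin_start, bin_end, count plus the recent
    (age <= recent_mya) count/fraction in ``DataFrame.attrs``.  Saturated
    and too-short elements are excluded (they carry no age).
    """
    cfg = cfg or DatingConfig()
    w = cfg.bin_width_mya
    dated = [a.age_mya for a in ages if a.status == "dated"]
    if not dated:
        df = pd.DataFrame(columns=["bin_start_mya", "bin_end_mya", "count"])
        df.attrs.update({"n_dated": 0, "recent_count": 0, "recent_fraction": None,
                         "recent_mya": recent_mya})
        return df
    n_bins = int(max(dated) // w) + 1
    counts = [0] * n_bins
    for age in dated:
        counts[min(int(age // w), n_bins - 1)] += 1
    df = pd.DataFrame(
        {
            "bin_start_mya": [i * w for i in range(n_bins)],
            "bin_end_mya": [(i + 1) * w for i in range(n_bins)],
            "count": counts,
        }
    )
    recent = sum(1 for a in dated if a <= recent_mya)
    df.attrs.update(
        {
            "n_dated": len(dated),
            "recent_count": recent,
            "recent_fraction": recent / len(dated),
            "recent_mya": recent_mya,
        }
    )
    return df
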