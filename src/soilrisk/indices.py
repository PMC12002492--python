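"""Contamination and health-risk indices for soil heavy-metal surveys.

Implements the standard screening indicators used to rate industrial soil
pollution against background and regulatory reference concentrations:

* ``CF = C_soil / C_background`` — contamination factor per element;
* ``PLI`` — pollution load index, the geometric mean of CFs over the detected
  elements, with elements at CF ≤ 0.7 excluded from both product and root;
* ``HQ = C_soil / MPC`` — hazard quotient; HQ > 1 flags possible adverse
  effects;
* ``Zc`` — total pollution indicator over the "anomalous" elements
  (CF ≥ 1.5).  The default ("literal") form is ``ΣCF − n − 1``; the classical
  Saet form ``ΣCF − (n − 1)`` is selectable and always exceeds it by 1;
* ``B`` — a 0–100 integral assessment score weighting exceedances by element
  toxicity, ``B = 100·Df/D`` with weights ``Ki = 1/MPC``, ``Df = ΣKi`` and
  ``D = Σ max(CF, 1)·Ki`` (elements below MPC are floored at their MPC, so
  only exceedances depress the score; B = 100 means toxicologically neutral
  soil).

Descriptive statistics follow survey-report conventions: non-detects count as
zeros, the coefficient of variation classifies the spatial regime (<33%
uniform, 33–64% random, >64% clustered), and report values round half-up to
two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .sample_io import ElementReference, SampleTable

__all__ = [
    "ClassificationScale",
    "PLI_SCALE",
    "ZC_SCALE",
    "round_half_up",
    "contamination_factor",
    "hazard_quotient",
    "pollution_load_index",
    "total_pollution_index",
    "integral_score",
    "descriptive_stats",
    "site_indices",
    "area_mean_indices",
    "classify",
]

PLI_EXCLUSION_CF = 0.7  # CFs at or below this never enter the PLI product
ZC_ANOMALY_CF = 1.5  # elements at or above this count as anomalous


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero, as printed survey tables do."""
    if not np.isfinite(value):
        return value
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ClassificationScale:
    """Ordered right-closed intervals mapping an index value to a class label.

    ``k`` breakpoints define ``k+1`` classes; a value exactly on a breakpoint
    takes the lower class, values above the last breakpoint take the final
    label.
    """

    name: str
    breakpoints: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self):
        bp = np.asarray(self.breakpoints, dtype=float)
        if len(self.labels) != len(bp) + 1:
            raise ValueError(f"{self.name}: need {len(bp) + 1} labels for {len(bp)} breakpoints")
        if len(bp) and not np.all(np.diff(bp) > 0):
            raise ValueError(f"{self.name}: breakpoints must be strictly increasing")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"{self.name}: labels must be unique")

    def class_index(self, value):
        value = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(value)):
            raise ValueError(f"{self.name}: cannot classify non-finite values")
        return np.searchsorted(np.asarray(self.breakpoints, dtype=float), value, side="left")


# Default scales.  The PLI breakpoints are the conventional load-index grades;
# the Zc grades are the standard sanitary categories anchored at the
# "permissible below 16" bound.
PLI_SCALE = ClassificationScale(
    name="pli",
    breakpoints=(0.0, 1.0, 3.0, 5.0),
    labels=(
        "no contamination",
        "low contamination",
        "moderate contamination",
        "considerable contamination",
        "very high contamination",
    ),
)

ZC_SCALE = ClassificationScale(
    name="zc",
    breakpoints=(16.0, 32.0, 128.0),
    labels=("permissible", "moderately hazardous", "hazardous", "extremely hazardous"),
)

DEFAULT_SCALES = {"pli": PLI_SCALE, "zc": ZC_SCALE}


def classify(value: float, scale: ClassificationScale) -> str:
    """Class label for a value on a right-closed scale."""
    return scale.labels[int(scale.class_index(value))]


def contamination_factor(conc: float, background: float) -> float:
    if not background > 0:
        raise ValueError(f"background must be positive, got {background}")
    if conc < 0:
        raise ValueError(f"concentration must be non-negative, got {conc}")
    return conc / background


def hazard_quotient(conc: float, mpc: float) -> float:
    if not mpc > 0:
        raise ValueError(f"MPC must be positive, got {mpc}")
    return conc / mpc


def pollution_load_index(
    cfs: dict[str, float] | pd.Series,
    detected: dict[str, bool] | pd.Series | None = None,
    exclusion_threshold: float = PLI_EXCLUSION_CF,
) -> tuple[float, int]:
    """Geometric mean of CFs over detected elements above the exclusion cut.

    ``n`` in the root counts only the surviving elements: non-detects never
    enter, nor do elements with CF ≤ ``exclusion_threshold``.  Returns
    ``(pli, n_used)``; ``(0.0, 0)`` if nothing survives.
    """
    cfs = pd.Series(cfs, dtype=float)
    if cfs.empty:
        raise ValueError("PLI needs at least one element")
    if detected is None:
        detected = cfs > 0
    else:
        detected = pd.Series(detected).reindex(cfs.index).fillna(False).astype(bool)
    surviving = cfs[detected & (cfs > exclusion_threshold)]
    if surviving.empty:
        return 0.0, 0
    return float(np.exp(np.mean(np.log(surviving.to_numpy())))), int(len(surviving))


def total_pollution_index(
    cfs: dict[str, float] | pd.Series,
    anomaly_threshold: float = ZC_ANOMALY_CF,
    variant: str = "literal",
) -> tuple[float, int]:
    """Total pollution indicator over the anomalous (CF ≥ threshold) elements.

    ``literal`` evaluates ``ΣCF − n − 1``; ``classical`` the Saet form
    ``ΣCF − (n − 1)``.  An empty anomaly set yields 0.
    """
    if variant not in ("literal", "classical"):
        raise ValueError(f"unknown Zc variant {variant!r}")
    cfs = pd.Series(cfs, dtype=float)
    anomalous = cfs[cfs >= anomaly_threshold]
    n = int(len(anomalous))
    if n == 0:
        return 0.0, 0
    total = float(anomalous.sum())
    zc = total - n - 1 if variant == "literal" else total - (n - 1)
    return zc, n


def integral_score(
    cfs: dict[str, float] | pd.Series,
    mpcs: dict[str, float] | pd.Series,
) -> tuple[float, float, float]:
    """Toxicity-weighted integral score ``(D, Df, B)``.

    All elements enter ``Df``; CFs not exceeding 1 are floored at 1 in ``D``,
    so only MPC exceedances move B below 100.
    """
    cfs = pd.Series(cfs, dtype=float)
    if cfs.empty:
        raise ValueError("integral score needs at least one element")
    mpcs = pd.Series(mpcs, dtype=float).reindex(cfs.index)
    if mpcs.isna().any() or not (mpcs > 0).all():
        raise ValueError("every element needs a positive MPC")
    ki = 1.0 / mpcs
    d_total = float((np.maximum(cfs, 1.0) * ki).sum())
    df_total = float(ki.sum())
    return d_total, df_total, 100.0 * df_total / d_total


def cv_regime(cv_percent: float) -> str:
    """Spatial-distribution regime from the coefficient of variation (%).

    Below 33% the element is spread uniformly, 33–64% randomly, above 64% in
    clusters (hotspots).
    """
    if cv_percent < 33.0:
        return "uniform"
    if cv_percent <= 64.0:
        return "random"
    return "clustered"


def descriptive_stats(
    table: SampleTable, registry: dict[str, ElementReference]
) -> pd.DataFrame:
    """Per-element summary statistics over all sites, non-detects as zeros.

    Returns a frame indexed by element with min/max/mean/median, sample sd,
    CV%, the integer-rounded share of sites above MPC, and the CV spatial
    regime.
    """
    if table.n_sites < 2:
        raise ValueError("descriptive statistics need at least 2 sites")
    conc = table.conc
    rows = {}
    for el in table.elements:
        x = conc[el].to_numpy(dtype=float)
        mean = float(x.mean())
        sd = float(x.std(ddof=1))
        cv = 100.0 * sd / mean if mean > 0 else 0.0
        over = np.nan
        if el in registry:
            over = round_half_up(100.0 * float((x > registry[el].mpc).sum()) / len(x), 0)
        rows[el] = {
            "min": float(x.min()),
            "max": float(x.max()),
            "mean": mean,
            "median": float(np.median(x)),
            "sd": sd,
            "cv_percent": cv,
            "pct_over_mpc": over,
            "cv_regime": cv_regime(cv),
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[table.elements]


def site_indices(
    table: SampleTable,
    registry: dict[str, ElementReference],
    scales: dict[str, ClassificationScale] | None = None,
    zc_variant: str = "literal",
) -> pd.DataFrame:
    """Full per-site index table.

    One row per site: ``cf_<el>`` and ``hq_<el>`` per element, then ``pli``,
    ``n_pli``, ``zc``, ``n_zc``, ``d``, ``df``, ``b_score`` and one
    ``<scale>_class`` label column per configured scale (PLI and Zc scales by
    default; negative literal Zc values simply classify as permissible).
    """
    scales = DEFAULT_SCALES if scales is None else scales
    missing = [el for el in table.elements if el not in registry]
    if missing:
        raise ValueError(f"elements without reference entries: {missing}")
    background = pd.Series({el: registry[el].background for el in table.elements})
    mpc = pd.Series({el: registry[el].mpc for el in table.elements})
    rows = []
    for site_id in table.site_ids:
        conc = table.conc.loc[site_id]
        cf = conc / background
        hq = conc / mpc
        pli, n_pli = pollution_load_index(cf, detected=conc > 0)
        zc, n_zc = total_pollution_index(cf, variant=zc_variant)
        d_total, df_total, b_score = integral_score(cf, mpc)
        row = {f"cf_{el}": cf[el] for el in table.elements}
        row |= {f"hq_{el}": hq[el] for el in table.elements}
        row |= {
            "pli": pli,
            "n_pli": n_pli,
            "zc": zc,
            "n_zc": n_zc,
            "d": d_total,
            "df": df_total,
            "b_score": b_score,
        }
        if "pli" in scales:
            row["pli_class"] = classify(pli, scales["pli"])
        if "zc" in scales:
            row["zc_class"] = classify(zc, scales["zc"])
        rows.append(pd.Series(row, name=site_id))
    return pd.DataFrame(rows)


def area_mean_indices(
    table: SampleTable,
    registry: dict[str, ElementReference],
    zc_variant: str = "literal",
) -> dict:
    """Area-aggregate indicator summary (the "average impact" table).

    Mean CF per element is the mean concentration over background; mean HQ the
    mean concentration over MPC.  Aggregate PLI/Zc/D/Df/B are evaluated on the
    mean-CF vector at reporting precision (2 d.p.), the convention such
    summary tables are printed with; full-precision aggregates are returned
    alongside.
    """
    conc = table.conc
    stats = pd.DataFrame(
        {
            "min": conc.min(),
            "max": conc.max(),
            "mean": conc.mean(),
            "median": conc.median(),
        }
    )
    return summarize_from_stats(stats, registry, elements=table.elements, zc_variant=zc_variant)


def summarize_from_stats(
    stats: pd.DataFrame,
    registry: dict[str, ElementReference],
    elements: list[str] | None = None,
    zc_variant: str = "literal",
) -> dict:
    """Area-aggregate summary from per-element summary statistics.

    Accepts any frame with ``mean``/``median``/``min``/``max`` concentration
    columns (e.g. a published summary table), so the aggregate indicator row
    can be reproduced without per-site data.
    """
    elements = list(stats.index) if elements is None else elements
    background = pd.Series({el: registry[el].background for el in elements})
    mpc = pd.Series({el: registry[el].mpc for el in elements})
    mean_conc = stats["mean"].reindex(elements)
    per_element = pd.DataFrame(
        {
            "background": background,
            "mean_hq": mean_conc / mpc,
            "mean_cf": mean_conc / background,
            "min_cf": stats["min"].reindex(elements) / background,
            "max_cf": stats["max"].reindex(elements) / background,
            "median_cf": stats["median"].reindex(elements) / background,
        }
    )
    # Aggregates on the reported-precision CF vector (how summary rows are
    # printed); the full-precision counterparts are kept for analysis.
    cf_reported = per_element["mean_cf"].map(round_half_up)
    pli, n_pli = pollution_load_index(cf_reported, detected=cf_reported > 0)
    zc, n_zc = total_pollution_index(cf_reported, variant=zc_variant)
    d_total, df_total, _ = integral_score(cf_reported, mpc)
    d_rep, df_rep = round_half_up(d_total), round_half_up(df_total)
    b_reported = round_half_up(100.0 * df_rep / d_rep)
    pli_full, _ = pollution_load_index(per_element["mean_cf"], detected=mean_conc > 0)
    zc_full, _ = total_pollution_index(per_element["mean_cf"], variant=zc_variant)
    d_full, df_full, b_full = integral_score(per_element["mean_cf"], mpc)
    return {
        "per_element": per_element,
        "pli": pli,
        "n_pli": n_pli,
        "zc": zc,
        "n_zc": n_zc,
        "d": d_total,
        "df": df_total,
        "b_score": b_reported,
        "full_precision": {
            "pli": pli_full,
            "zc": zc_full,
            "d": d_full,
            "df": df_full,
            "b_score": b_full,
        },
    }
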