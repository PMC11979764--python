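"""Polysome quantification from sucrose-gradient OD254 traces.

The fraction of ribosomes engaged in polysomes proxies global translational
potential. Given an absorbance trace with annotated regions (free material,
40S, 60S, monosome, polysome), the percent polysomes is the baseline-
subtracted polysome area over the total ribosome area (40S + 60S +
monosome + polysome), and per-sample values are reported relative to a
control condition fixed at 100% (the 20 degC sample in the heat-stress
design).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats

__all__ = [
    "AbsorbanceTrace",
    "PolysomeQuant",
    "RIBOSOME_REGIONS",
    "quantify_polysomes",
    "normalize_to_control",
]

#: regions whose areas sum to "total ribosomes"
RIBOSOME_REGIONS = ("s40", "s60", "monosome", "polysome")


@dataclass
class AbsorbanceTrace:
    """Ordered (position, OD254) samples with annotated regions.

    ``regions`` maps region names to (start, end) position intervals;
    they must be non-overlapping and ordered. ``baseline`` is either
    ``"linear"`` (straight line between the trace values at each region's
    endpoints, the chart-recorder convention) or a constant OD value.
    """

    position: np.ndarray
    od: np.ndarray
    regions: dict[str, tuple[float, float]]
    baseline: str | float = "linear"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.position.shape != self.od.shape or self.position.ndim != 1:
            raise ValueError("position and od must be matching 1-D arrays")
        if not (np.diff(self.position) > 0).all():
            raise ValueError("positions must be strictly increasing")
        spans = sorted(self.regions.values())
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if a1 > b0:
                raise ValueError("regions overlap")
        missing = [r for r in RIBOSOME_REGIONS if r not in self.regions]
        if missing:
            raise ValueError(f"missing ribosome regions: {missing}")

    def region_area(self, name: str) -> float:
        """Baseline-subtracted (clipped at 0) trapezoidal area of a region."""
        lo, hi = self.regions[name]
        mask = (self.position >= lo) & (self.position <= hi)
        if mask.sum() < 2:
            raise ValueError(f"region {name!r} covers fewer than 2 samples")
        x = self.position[mask]
        y = self.od[mask]
        if self.baseline == "linear":
            base = np.interp(x, [x[0], x[-1]], [y[0], y[-1]])
        else:
            base = float(self.baseline) * np.ones_like(y)
        return float(integrate.trapezoid(np.clip(y - base, 0.0, None), x))


@dataclass
class PolysomeQuant:
    """Areas and percent polysomes for one gradient."""

    area_polysomes: float
    area_total_ribosomes: float
    percent: float

    @property
    def areas_consistent(self) -> bool:
        return 0.0 <= self.percent <= 100.0


def quantify_polysomes(trace: AbsorbanceTrace) -> PolysomeQuant:
    """Percent polysomes = 100 x polysome area / total ribosome area."""
    areas = {r: trace.region_area(r) for r in RIBOSOME_REGIONS}
    total = sum(areas.values())
    if total <= 0:
        raise ValueError("zero total-ribosome area: nothing above baseline")
    poly = areas["polysome"]
    return PolysomeQuant(area_polysomes=poly, area_total_ribosomes=total,
                         percent=100.0 * poly / total)


def normalize_to_control(percents: pd.DataFrame,
                         control_label: str) -> pd.DataFrame:
    """Express percent-polysome values relative to a control condition.

    ``percents`` needs columns ``label`` and ``percent`` (one row per
    replicate gradient). The control's replicate-mean percent is set to
    100; each sample's replicates are rescaled by the same factor, and the
    per-label mean, SD, n and a two-sample t-test p-value against the
    control replicates are reported.
    """
    if "label" not in percents or "percent" not in percents:
        raise ValueError("percents needs 'label' and 'percent' columns")
    if control_label not in set(percents["label"]):
        raise ValueError(f"control label {control_label!r} not present")
    ctrl = percents.loc[percents["label"] == control_label, "percent"].to_numpy()
    ctrl_mean = float(ctrl.mean())
    if ctrl_mean == 0:
        raise ValueError("control percent is zero; cannot normalise")
    rows = []
    for label, grp in percents.groupby("label", sort=False):
        vals = 100.0 * grp["percent"].to_numpy() / ctrl_mean
        if label == control_label or len(vals) < 2 or len(ctrl) < 2:
            p = np.nan
        else:
            p = float(stats.ttest_ind(100.0 * ctrl / ctrl_mean, vals).pvalue)
        rows.append({"label": label,
                     "percent_vs_control": float(vals.mean()),
                     "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                     "n": len(vals),
                     "p_value_vs_control": p})
    return pd.DataFrame(rows).set_index("label")
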