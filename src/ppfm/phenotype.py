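"""The quantitative antifungal phenotype statistic.

Fungal growth inhibition on a half-inoculated plate is scored by comparing
the fungal growth radius toward the inoculated half (ir) with the radius
toward the non-inoculated control half (cr):

    inhibition% = 100 x (cr - ir) / cr

The statistic is 0 when growth is unaffected, 100 when growth toward the
bacterium is fully suppressed, and negative when the bacterium stimulates
growth (ir > cr); negative values are reported as-is, flagged, never
clamped. Technical replicates are aggregated by arithmetic mean with the
sample standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class InhibitionMeasurement:
    cr: float  # radius toward the non-inoculated half
    ir: float  # radius toward the inoculated half
    replicate: int = 1

    def __post_init__(self):
        if self.cr <= 0:
            raise ValueError("cr (control radius) must be positive")
        if self.ir < 0:
            raise ValueError("ir (inoculated-side radius) must be non-negative")


def inhibition_percent(m: InhibitionMeasurement) -> float:
    """100 x (cr - ir) / cr; negative when growth is stimulated."""
    return 100.0 * (m.cr - m.ir) / m.cr


def summarize_inhibition(plates: pd.DataFrame) -> pd.DataFrame:
    """Per-strain mean inhibition % and standard deviation over replicates.

    ``plates`` needs columns strain, replicate, cr, ir. The output flags
    strains whose mean is negative (growth stimulation).
    """
    required = {"strain", "replicate", "cr", "ir"}
    if not required <= set(plates.columns):
        raise ValueError(f"plates table needs columns {sorted(required)}")
    values = plates.assign(
        inhibition_pct=[
            inhibition_percent(InhibitionMeasurement(cr=row.cr, ir=row.ir))
            for row in plates.itertuples()
        ]
    )
    out = (
        values.groupby("strain")["inhibition_pct"]
        .agg(mean_inhibition_pct="mean", sd_inhibition_pct="std", n_replicates="count")
        .reset_index()
    )
    out["stimulation_flag"] = out["mean_inhibition_pct"] < 0
    return out
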