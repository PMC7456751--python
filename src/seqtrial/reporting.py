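"""Design reports and sample-size tables in the trial-protocol layout.

`render_sample_size_table` lays out per-arm and total sample sizes with
effect rows and (allocation x power) column groups, the format trial
protocols print.  `boundary_table` tabulates the per-look stopping
boundaries on the z and nominal-p scales together with the cumulative
spend.  `design_report` bundles every resolved input and decision so a
design can be reproduced from its report alone.
"""

from __future__ import annotations

import json
from typing import Sequence

import pandas as pd

from .boundaries import GSBoundaries, crossing_probabilities
from .samplesize import (
    DesignInput,
    group_sequential_sample_size,
    inflate_for_dropout,
)
from .spending import cumulative_spend

__all__ = [
    "render_sample_size_table",
    "boundary_table",
    "design_report",
]


def render_sample_size_table(grid: Sequence[DesignInput]) -> pd.DataFrame:
    """Sample-size table over a grid of designs.

    Rows: one per (p0, p1) with N1/N2/Total sub-rows; columns: one per
    (allocation, power) combination present in the grid.  Cells with an
    infeasible design (zero or negative benefit after orienting the
    direction) hold "NA".
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty design grid")
    effects = sorted({(d.p0, d.p1) for d in grid})
    columns = sorted(
        {(d.allocation, d.power) for d in grid},
        key=lambda c: (c[0][1] / c[0][0], c[1]),
    )
    col_names = [
        f"{a[0]}:{a[1]} ratio, power {int(round(pw * 100))}%" for a, pw in columns
    ]
    rows = []
    index = []
    by_key = {
        ((d.p0, d.p1), (d.allocation, d.power)): d for d in grid
    }
    for eff in effects:
        cells = {}
        for col, cname in zip(columns, col_names):
            d = by_key.get((eff, col))
            if d is None:
                cells[cname] = (None, None, None)
                continue
            try:
                res = group_sequential_sample_size(d)
                cells[cname] = (res.n1, res.n2, res.total)
            except ValueError:
                cells[cname] = (None, None, None)
        for i, part in enumerate(("N1", "N2", "Total")):
            index.append((f"p0={eff[0]:g}, p1={eff[1]:g}", part))
            rows.append(
                {
                    cname: ("NA" if cells[cname][i] is None else cells[cname][i])
                    for cname in col_names
                }
            )
    return pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["effect", "quantity"])
    )


def boundary_table(boundaries: GSBoundaries) -> pd.DataFrame:
    """Per-look boundary table: z, nominal p (3-decimal and full), spend."""
    fr = boundaries.schedule.fractions
    a_spec = boundaries.alpha_spec
    b_spec = boundaries.beta_spec
    rows = []
    for k, t in enumerate(fr):
        final = k == len(fr) - 1
        rows.append(
            {
                "look": k + 1,
                "information_fraction": t,
                "efficacy_z": boundaries.efficacy_z[k],
                "efficacy_p": round(boundaries.efficacy_p[k], 3),
                "efficacy_p_full": boundaries.efficacy_p[k],
                "futility_z": None if final else boundaries.futility_z[k],
                "futility_p": None if final else round(boundaries.futility_p[k], 3),
                "futility_p_full": None if final else boundaries.futility_p[k],
                "cumulative_alpha_spend": cumulative_spend(t, a_spec),
                "cumulative_beta_spend": cumulative_spend(t, b_spec),
            }
        )
    return pd.DataFrame(rows)


def design_report(
    design: DesignInput, dropout_fraction: float = 0.05
) -> dict:
    """Machine-readable record of a resolved design.

    Contains all inputs, resolved conventions (spending exponents,
    binding flag, rounding rule, block-size policy), the boundary table
    and the (raw and inflated) sample sizes; serializable with
    ``json.dumps``.
    """
    res = group_sequential_sample_size(design)
    inflated = inflate_for_dropout(res, dropout_fraction)
    bt = boundary_table(res.boundaries)
    cp = crossing_probabilities(res.boundaries, res.boundaries.drift)
    report = {
        "inputs": {
            "p0": design.p0,
            "p1": design.p1,
            "alpha_one_sided": design.alpha,
            "power": design.power,
            "allocation": list(design.allocation),
            "schedule": list(design.schedule.fractions),
            "rho_efficacy": design.rho_eff,
            "rho_futility": design.rho_fut,
            "direction": design.direction,
        },
        "conventions": {
            "binding_futility": design.binding,
            "variance": "unpooled, no continuity correction",
            "rounding": "ceiling per arm after continuous solve; "
            "n2 = ceiling(ratio * n1)",
            "block_sizes": "1:1 random {4,6}; 1:2 fixed 6",
        },
        "boundaries": bt.to_dict(orient="records"),
        "drift": res.boundaries.drift,
        "sample_size": {
            "n1": res.n1,
            "n2": res.n2,
            "total": res.total,
            "per_look_enrollment": [list(e) for e in res.per_look_enrollment],
            "attained_power": res.attained_power,
        },
        "inflated_sample_size": {
            "fraction": dropout_fraction,
            "n1": inflated.n1,
            "n2": inflated.n2,
            "total": inflated.total,
        },
        "power_check": {
            "efficacy_crossing_at_design_drift": cp.total_efficacy,
            "per_look_efficacy": list(cp.efficacy),
            "per_look_futility": list(cp.futility),
        },
    }
    json.dumps(report)  # fail fast if anything is not serializable
    return report
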