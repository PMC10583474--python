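"""Primary and secondary cohort outcome analyses.

Primary: how well do post-modulation FRFxV%, FRLV%, sFLR% and KGR predict
severe post-hepatectomy liver failure (PHLF grade >= B)? All four are scored
lower-is-positive (a small or slow-growing remnant predicts failure), so an
AUC above 0.5 means the predictor works in the clinically expected direction.

Secondary: ALPPS versus PVE contrast of anatomic and functional volumetry —
rapid ALPPS hypertrophy inflates anatomic growth (iFRL) without a matching
functional gain (iFRFx).

Raw Mann-Whitney p-values are reported without multiple-testing correction;
the tables carry a note to that effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .stats import RocCurve, mann_whitney_u, roc_auc
from .types import Technique
from .volumetry import VolumetryRecord

__all__ = [
    "PREDICTORS",
    "TECHNIQUE_TABLE_ROWS",
    "PrimaryOutcome",
    "primary_outcome",
    "secondary_outcome",
    "MULTIPLICITY_NOTE",
]

MULTIPLICITY_NOTE = "p-values are raw (no multiple-testing correction applied)"

#: predictor name -> VolumetryRecord field carrying the post-modulation score
PREDICTORS: dict[str, str] = {
    "FRFxV": "frfxv_post_pct",
    "FRLV": "frlv_post_pct",
    "sFLR": "sflr_post_pct",
    "KGR": "kgr_pct_per_day",
}

#: severity-split descriptive rows (field, printed label)
_PHLF_ROWS = [
    ("frl_post_cc", "FRL (cc)"),
    ("frfx_post_cc", "FRFx (cc)"),
    ("frlv_post_pct", "FRLV (%)"),
    ("frfxv_post_pct", "FRFxV (%)"),
    ("ifrl_pct", "iFRL (%)"),
    ("ifrfx_pct", "iFRFx (%)"),
    ("sflr_post_pct", "sFLR (%)"),
    ("kgr_pct_per_day", "KGR (%/day)"),
]

#: ALPPS-vs-PVE volumetric comparison row schema
TECHNIQUE_TABLE_ROWS = [
    ("tlv_cc", "TLVpre (cc)"),
    ("frl_pre_cc", "FRLpre (cc)"),
    ("frfx_pre_cc", "FRFxpre (cc)"),
    ("frlv_pre_pct", "FRLVpre (%)"),
    ("frfxv_pre_pct", "FRFxVpre (%)"),
    ("frl_post_cc", "FRLpost (cc)"),
    ("frfx_post_cc", "FRFxpost (cc)"),
    ("frlv_post_pct", "FRLVpost (%)"),
    ("frfxv_post_pct", "FRFxVpost (%)"),
    ("ifrl_pct", "iFRL (%)"),
    ("ifrfx_pct", "iFRFx (%)"),
]


def _median_range(v: np.ndarray) -> str:
    if v.size == 0:
        return "NA"
    return f"{np.median(v):.2f} ({v.min():.2f}-{v.max():.2f})"


@dataclass
class PrimaryOutcome:
    """Severity-split medians and per-predictor ROC curves."""

    table: pd.DataFrame
    roc: dict[str, RocCurve]
    n_severe: int
    n_mild: int
    note: str = MULTIPLICITY_NOTE

    @property
    def aucs(self) -> dict[str, float]:
        return {k: r.auc for k, r in self.roc.items()}


def primary_outcome(
    records: Sequence[VolumetryRecord],
    severe: Sequence[bool],
) -> PrimaryOutcome:
    """PHLF >= B prediction: ROC per predictor plus a severity-split table.

    ``severe`` flags PHLF grade >= B per case (aligned with ``records``).
    Degenerate groups (fewer than 2 cases on either side) yield NA rows and
    no ROC curves rather than being dropped silently.
    """
    severe = np.asarray(severe, dtype=bool)
    if len(records) != severe.size:
        raise ValueError("records and severity flags must align")
    df = pd.DataFrame(
        {f: [getattr(r, f) for r in records] for f, _ in _PHLF_ROWS}
    )
    n_severe = int(severe.sum())
    n_mild = int((~severe).sum())
    degenerate = min(n_severe, n_mild) < 2

    rows = []
    for fld, label in _PHLF_ROWS:
        v = df[fld].to_numpy()
        if degenerate:
            p = np.nan
        else:
            _, p = mann_whitney_u(v[~severe], v[severe])
        rows.append(
            {
                "quantity": label,
                "phlf_lt_b": _median_range(v[~severe]),
                "phlf_ge_b": _median_range(v[severe]),
                "p_mann_whitney": p,
            }
        )
    roc: dict[str, RocCurve] = {}
    if not degenerate:
        for name, fld in PREDICTORS.items():
            roc[name] = roc_auc(df[fld].to_numpy(), severe, direction="lower")
    return PrimaryOutcome(
        table=pd.DataFrame(rows), roc=roc, n_severe=n_severe, n_mild=n_mild
    )


def secondary_outcome(
    records: Sequence[VolumetryRecord],
    techniques: Sequence[str],
) -> pd.DataFrame:
    """ALPPS-vs-PVE volumetric contrast with Mann-Whitney p per row."""
    tech = np.asarray(techniques)
    if len(records) != tech.size:
        raise ValueError("records and techniques must align")
    is_alpps = tech == Technique.ALPPS
    if not is_alpps.any() or is_alpps.all():
        raise ValueError("both techniques must be present")
    df = pd.DataFrame(
        {f: [getattr(r, f) for r in records] for f, _ in TECHNIQUE_TABLE_ROWS}
    )
    rows = []
    for fld, label in TECHNIQUE_TABLE_ROWS:
        v = df[fld].to_numpy()
        a, p_vals = v[is_alpps], v[~is_alpps]
        _, p = mann_whitney_u(a, p_vals)
        rows.append(
            {
                "quantity": label,
                "alpps": _median_range(a),
                "pve": _median_range(p_vals),
                "alpps_median": float(np.median(a)),
                "pve_median": float(np.median(p_vals)),
                "p_mann_whitney": p,
            }
        )
    return pd.DataFrame(rows)
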