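"""Small quantitative procedures outside the methylome core: threshold
classification of splice events and the ELISA standard-curve conversion
for global percent 5-methylcytosine.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd


@dataclasses.dataclass
class SpliceEvent:
    event_id: str
    psi_control: float
    psi_case: float
    delta_psi: float  # control - case
    inclusion_class: str  # included / excluded / intermediate
    aberrance: str  # down / up / unchanged


def classify_splice_events(
    psi: pd.DataFrame,
    orientation: str = "control_minus_case",
) -> list[SpliceEvent]:
    """Threshold classification of exon-inclusion (PSI) values.

    The inclusion class comes from the control PSI (>= 0.9 included,
    <= 0.1 excluded, else intermediate).  Aberrance comes from
    delta-PSI = control - case: > 0.1 means inclusion is reduced in cases
    ("down"), < -0.1 increased ("up"), else "unchanged".  Pass
    ``orientation="case_minus_control"`` to flip the convention.
    """
    required = {"event_id", "psi_control", "psi_case"}
    missing = required - set(psi.columns)
    if missing:
        raise ValueError(f"PSI table missing columns: {sorted(missing)}")
    if orientation not in ("control_minus_case", "case_minus_control"):
        raise ValueError(f"unknown orientation {orientation!r}")
    events = []
    for row in psi.itertuples(index=False):
        pc, pa = float(row.psi_control), float(row.psi_case)
        for name, value in (("psi_control", pc), ("psi_case", pa)):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1] for {row.event_id}")
        dpsi = pc - pa if orientation == "control_minus_case" else pa - pc
        if pc >= 0.9:
            inclusion = "included"
        elif pc <= 0.1:
            inclusion = "excluded"
        else:
            inclusion = "intermediate"
        if dpsi > 0.1:
            aberrance = "down"
        elif dpsi < -0.1:
            aberrance = "up"
        else:
            aberrance = "unchanged"
        events.append(
            SpliceEvent(
                event_id=str(row.event_id),
                psi_control=pc,
                psi_case=pa,
                delta_psi=dpsi,
                inclusion_class=inclusion,
                aberrance=aberrance,
            )
        )
    return events


def splice_events_table(events: list[SpliceEvent]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(e) for e in events])


@dataclasses.dataclass
class ElisaFit:
    coefficients: tuple  # (a, b, c) in percent = a + b*ln(A) + c*ln(A)^2
    residuals: np.ndarray  # per-standard fit residuals (percent units)

    def predict(self, absorbance) -> np.ndarray:
        absorbance = np.asarray(absorbance, dtype=float)
        if np.any(absorbance <= 0):
            raise ValueError("absorbance must be positive")
        a, b, c = self.coefficients
        log_a = np.log(absorbance)
        return a + b * log_a + c * log_a**2


def fit_elisa_standard(percent_5mc, absorbance_405) -> ElisaFit:
    """Least-squares quadratic-in-log-absorbance standard curve:
    percent = a + b*ln(A) + c*ln(A)^2.  Needs >= 3 standards."""
    pct = np.asarray(percent_5mc, dtype=float)
    absb = np.asarray(absorbance_405, dtype=float)
    if pct.size != absb.size:
        raise ValueError("percent and absorbance lengths differ")
    if pct.size < 3:
        raise ValueError("need >= 3 standards for a second-order fit")
    if np.any(absb <= 0):
        raise ValueError("absorbance must be positive (log-transformable)")
    log_a = np.log(absb)
    design = np.column_stack([np.ones_like(log_a), log_a, log_a**2])
    coef, *_ = np.linalg.lstsq(design, pct, rcond=None)
    fit = ElisaFit(coefficients=tuple(float(x) for x in coef), residuals=np.empty(0))
    fit.residuals = pct - fit.predict(absb)
    return fit


def elisa_percent_5mc(
    standards: pd.DataFrame,
    sample_absorbances: pd.DataFrame,
) -> tuple[pd.DataFrame, ElisaFit]:
    """Per-sample percent 5-mC from triplicate absorbances.

    ``standards`` needs columns percent_5mc and absorbance_405;
    ``sample_absorbances`` needs sample_id plus one or more absorbance
    columns (replicates).  The fit is evaluated at each sample's mean
    replicate absorbance.
    """
    fit = fit_elisa_standard(
        standards["percent_5mc"], standards["absorbance_405"]
    )
    reps = sample_absorbances.drop(columns=["sample_id"])
    mean_abs = reps.mean(axis=1).to_numpy(dtype=float)
    out = pd.DataFrame(
        {
            "sample_id": sample_absorbances["sample_id"],
            "mean_absorbance": mean_abs,
            "percent_5mc": fit.predict(mean_abs),
        }
    )
    return out, fit
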