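"""Exposure-response functions linking WBGT to the fraction of work time lost.

The ERF is a cumulative normal: at wet-bulb globe temperature ``w`` a worker
at metabolic intensity ``I`` loses the fraction

    loss(w; I) = 1/2 * (1 + erf((w - Prodmean_I) / (Prodsd_I * sqrt(2))))

of each work hour, i.e. the normal CDF with location ``Prodmean`` (the WBGT
at which half the work capacity is lost) and scale ``Prodsd``.  Three
intensity classes are used: 200 W (light; service), 300 W (moderate;
manufacturing) and 400 W (heavy; agriculture and construction).

Two parameter sources are combined:

* ``standard-fit`` — parameters fitted to work/rest-ratio tables from an
  occupational health standard (one curve per intensity);
* ``global-anchor`` — an epidemiologically derived 300 W curve.

``calibrate_chinese_erf`` transfers the standard's between-intensity offsets
onto the epidemiological 300 W anchor, yielding a ``calibrated`` set whose
300 W curve equals the anchor exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import erf as _erf

INTENSITIES = (200, 300, 400)

#: metabolic intensity (W) assumed for each employment sector
SECTOR_INTENSITY = {
    "agriculture": 400,
    "construction": 400,
    "manufacturing": 300,
    "service": 200,
}

#: work setting per sector; air conditioning shields only indoor sectors
SECTOR_SETTING = {
    "agriculture": "outdoor",
    "construction": "outdoor",
    "manufacturing": "indoor",
    "service": "indoor",
}


class ERFError(ValueError):
    """Raised for invalid ERF parameters or a failed fit/calibration."""


@dataclass(frozen=True)
class ERFParams:
    """Normal-CDF exposure-response parameters per work intensity.

    Parameters
    ----------
    prodmean, prodsd : dict
        Mapping intensity (W) -> location / scale in deg C.  All three
        intensities (200, 300, 400 W) must be present and every scale
        positive.
    provenance : str
        One of ``standard-fit``, ``global-anchor``, ``calibrated`` (or a
        free-form label for synthetic truth sets).
    """

    prodmean: dict[int, float]
    prodsd: dict[int, float]
    provenance: str = "standard-fit"
    fit_report: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for i in INTENSITIES:
            if i not in self.prodmean or i not in self.prodsd:
                raise ERFError(f"missing intensity {i} W in ERF parameters")
            if not np.isfinite(self.prodmean[i]):
                raise ERFError(f"non-finite Prodmean at {i} W")
            if not (self.prodsd[i] > 0):
                raise ERFError(f"Prodsd must be > 0 at {i} W, got {self.prodsd[i]}")

    def mean(self, intensity: int) -> float:
        return self.prodmean[_check_intensity(intensity)]

    def sd(self, intensity: int) -> float:
        return self.prodsd[_check_intensity(intensity)]

    def as_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "intensities": {
                str(i): {"prodmean": float(self.prodmean[i]), "prodsd": float(self.prodsd[i])}
                for i in INTENSITIES
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ERFParams":
        ints = d["intensities"]
        return cls(
            prodmean={int(i): float(v["prodmean"]) for i, v in ints.items()},
            prodsd={int(i): float(v["prodsd"]) for i, v in ints.items()},
            provenance=d.get("provenance", "standard-fit"),
        )


def _check_intensity(intensity: int) -> int:
    if intensity not in INTENSITIES:
        raise ERFError(f"unknown work intensity {intensity!r}; expected one of {INTENSITIES}")
    return intensity


def loss_fraction(wbgt, intensity: int, params: ERFParams):
    """Fraction of work time lost at a given WBGT and work intensity.

    Evaluates the normal CDF with mean ``Prodmean`` and sd ``Prodsd`` of the
    given intensity.  Accepts scalars or arrays; strictly increasing in WBGT
    with limits 0 and 1.
    """
    m = params.mean(intensity)
    s = params.sd(intensity)
    z = (np.asarray(wbgt, dtype=float) - m) / (s * np.sqrt(2.0))
    out = 0.5 * (1.0 + _erf(z))
    return out if out.ndim else float(out)


def _cdf(w, m, s):
    return 0.5 * (1.0 + _erf((w - m) / (s * np.sqrt(2.0))))


def fit_workrest_cdf(table: pd.DataFrame) -> ERFParams:
    """Fit (Prodmean, Prodsd) per intensity to a work/rest table.

    The table has columns ``intensity_w``, ``wbgt_c``, ``work_fraction``;
    the observed loss is ``1 - work_fraction`` and the fit minimizes the sum
    of squared residuals between it and the normal CDF, by nonlinear least
    squares.  Initialization: location at the WBGT point with loss closest to
    0.5; scale from half the WBGT span between the points with losses nearest
    0.16 and 0.84; scale bounded to (0.1, 20) deg C.

    Returns ``ERFParams`` with provenance ``standard-fit`` and a per-intensity
    fit report (residual norm, iterations) in ``fit_report``.
    """
    validate_workrest_table(table)
    means: dict[int, float] = {}
    sds: dict[int, float] = {}
    report: dict = {}
    for intensity, grp in table.groupby("intensity_w"):
        intensity = int(intensity)
        w = grp["wbgt_c"].to_numpy(dtype=float)
        loss = 1.0 - grp["work_fraction"].to_numpy(dtype=float)
        if np.ptp(loss) == 0.0:
            raise ERFError(
                f"degenerate work/rest table at {intensity} W: constant work_fraction"
            )
        m0 = w[np.argmin(np.abs(loss - 0.5))]
        s0 = 0.5 * abs(
            w[np.argmin(np.abs(loss - 0.84))] - w[np.argmin(np.abs(loss - 0.16))]
        )
        s0 = min(max(s0, 0.2), 19.0)
        res = least_squares(
            lambda p: _cdf(w, p[0], p[1]) - loss,
            x0=[m0, s0],
            bounds=([-100.0, 0.1], [100.0, 20.0]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if not res.success:
            raise ERFError(
                f"CDF fit failed to converge at {intensity} W: {res.message}"
            )
        means[intensity] = float(res.x[0])
        sds[intensity] = float(res.x[1])
        report[intensity] = {
            "residual_norm": float(np.linalg.norm(res.fun)),
            "nfev": int(res.nfev),
        }
    return ERFParams(prodmean=means, prodsd=sds, provenance="standard-fit", fit_report=report)


def calibrate_chinese_erf(
    standard: ERFParams,
    anchor300: tuple[float, float],
    sd_mode: str = "offset",
) -> ERFParams:
    """Transfer the standard fit's intensity offsets onto a 300 W anchor.

    The calibrated 300 W parameters equal ``anchor300`` exactly; 200 W and
    400 W are the anchor plus the standard fit's (200-300) and (400-300)
    parameter differences.  ``sd_mode="offset"`` transfers sd differences the
    same way; ``sd_mode="anchor"`` reuses the anchor sd for all intensities.
    """
    am, asd = float(anchor300[0]), float(anchor300[1])
    if not (asd > 0) or not np.isfinite(am):
        raise ERFError(f"invalid 300 W anchor {anchor300!r}")
    if sd_mode not in ("offset", "anchor"):
        raise ERFError(f"unknown sd_mode {sd_mode!r}; use 'offset' or 'anchor'")
    means = {i: am + (standard.mean(i) - standard.mean(300)) for i in INTENSITIES}
    if sd_mode == "offset":
        sds = {i: asd + (standard.sd(i) - standard.sd(300)) for i in INTENSITIES}
    else:
        sds = {i: asd for i in INTENSITIES}
    for i, s in sds.items():
        if not (s > 0):
            raise ERFError(
                f"calibration yields non-positive Prodsd {s} at {i} W; "
                "consider sd_mode='anchor'"
            )
    return ERFParams(prodmean=means, prodsd=sds, provenance="calibrated")


def validate_workrest_table(table: pd.DataFrame) -> None:
    """Schema and invariant checks for a work/rest table; raises ERFError."""
    required = {"intensity_w", "wbgt_c", "work_fraction"}
    missing = required - set(table.columns)
    if missing:
        raise ERFError(f"work/rest table missing column(s): {sorted(missing)}")
    wf = table["work_fraction"].to_numpy(dtype=float)
    if np.any(wf < 0) or np.any(wf > 1) or np.any(~np.isfinite(wf)):
        raise ERFError("column 'work_fraction' must lie in [0, 1]")
    bad = set(table["intensity_w"].unique()) - set(INTENSITIES)
    if bad:
        raise ERFError(f"column 'intensity_w' has unknown intensities {sorted(bad)}")
    for intensity, grp in table.groupby("intensity_w"):
        if grp["wbgt_c"].nunique() < 4:
            raise ERFError(
                f"need >= 4 distinct WBGT points at {intensity} W "
                f"(got {grp['wbgt_c'].nunique()}); fit would be under-determined"
            )
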