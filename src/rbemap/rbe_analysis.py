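"""RBE at fixed survival levels, profiles over beam quality, and overkill.

RBE at a surviving-fraction level s is the ratio of isosurvival doses,

    RBE(s) = D_photon(s) / D_ion(s),

each dose obtained by inverting its fitted LQ curve.  The standard error
propagates both fits' (alpha, beta) covariances through the isosurvival
dose by the delta method (the two fits come from independent irradiations,
so no cross-covariance).  Profiles index the per-column estimates by the
dose-mean lineal energy y_d of each column, locate the peak, and test for
the overkill signature: a maximum at an interior beam quality followed by
strictly lower effectiveness beyond it.

An estimate whose isosurvival dose lies beyond the dose range covered by
above-detection-limit survival data is marked excluded rather than
extrapolated, matching how published tables flag such entries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .lq_model import LQFit, LQFitError, dose_at_sf, fit_lq_poisson
from .plate_io import PlateExperiment, TableFixture
from .survival_stats import (
    PlatingEfficiency,
    limit_of_detection,
    pool_plating_efficiency,
    surviving_fractions,
)


class RBEError(ValueError):
    """Raised for invalid RBE computations."""


@dataclass(frozen=True)
class RBEEstimate:
    """RBE at one surviving-fraction level, with delta-method SE.

    Excluded estimates (no data coverage at the requested level) carry no
    rbe value and record the reason.
    """

    sf_level: float
    rbe: Optional[float]
    se: Optional[float]
    excluded: bool = False
    reason: Optional[str] = None
    reference_fit: Optional[LQFit] = None
    ion_fit: Optional[LQFit] = None

    def __post_init__(self) -> None:
        if self.excluded and self.rbe is not None:
            raise RBEError("excluded estimates must not carry an rbe value")
        if self.rbe is not None and self.rbe <= 0:
            raise RBEError(f"rbe must be positive, got {self.rbe}")
        if self.se is not None and self.se < 0:
            raise RBEError("se must be non-negative")


def _isodose_gradient(fit: LQFit, sf_level: float) -> tuple[float, np.ndarray]:
    """Isosurvival dose D and its gradient w.r.t. (alpha, beta).

    Differentiating alpha*D + beta*D^2 = -ln(s) implicitly:
        dD/dalpha = -D / (alpha + 2 beta D)
        dD/dbeta  = -D^2 / (alpha + 2 beta D)
    """
    D = dose_at_sf(fit, sf_level)
    denom = fit.alpha + 2.0 * fit.beta * D
    return D, np.array([-D / denom, -(D * D) / denom])


def rbe_se_delta(reference: LQFit, ion: LQFit, sf_level: float) -> Optional[float]:
    """First-order (delta-method) standard error of RBE(sf_level).

    se = RBE * sqrt(g' S g / D_ref^2 + h' W h / D_ion^2) with g, h the
    gradients of the two isosurvival doses and S, W the fit covariances.
    Returns None when either covariance has an unavailable (boundary-pinned)
    component, in which case the point estimate is still meaningful.
    """
    d_ref, g = _isodose_gradient(reference, sf_level)
    d_ion, h = _isodose_gradient(ion, sf_level)
    rbe = d_ref / d_ion
    var_terms = []
    for grad, cov, d in ((g, reference.covariance, d_ref), (h, ion.covariance, d_ion)):
        if np.isnan(cov).any():
            # a boundary-pinned parameter has no Wald variance: SE unavailable
            return None
        var_terms.append(float(grad @ cov @ grad) / (d * d))
    total = sum(var_terms)
    if total < 0:
        total = 0.0
    return abs(rbe) * math.sqrt(total)


def compute_rbe(
    reference: LQFit,
    ion: LQFit,
    sf_level: float,
    enforce_coverage: bool = True,
) -> RBEEstimate:
    """RBE at one survival level: D_reference(s) / D_ion(s), with SE.

    When the ion fit records ``max_dose_covered`` and the isosurvival dose
    exceeds it, the estimate is excluded for lack of data coverage instead
    of being extrapolated.
    """
    if not 0 < sf_level < 1:
        raise RBEError(f"sf_level must be in (0, 1), got {sf_level}")
    d_ref = dose_at_sf(reference, sf_level)
    d_ion = dose_at_sf(ion, sf_level)
    if (
        enforce_coverage
        and ion.max_dose_covered is not None
        and d_ion > ion.max_dose_covered
    ):
        return RBEEstimate(
            sf_level=sf_level,
            rbe=None,
            se=None,
            excluded=True,
            reason=(
                f"isosurvival dose {d_ion:.3g} Gy beyond data coverage "
                f"({ion.max_dose_covered:.3g} Gy)"
            ),
            reference_fit=reference,
            ion_fit=ion,
        )
    return RBEEstimate(
        sf_level=sf_level,
        rbe=d_ref / d_ion,
        se=rbe_se_delta(reference, ion, sf_level),
        reference_fit=reference,
        ion_fit=ion,
    )


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProfilePoint:
    column_index: int
    y_d: float
    estimates: dict[float, RBEEstimate]


@dataclass
class RBEProfile:
    """RBE-vs-beam-quality profile for one cell line and ion.

    Points are ordered by column index (increasing depth along the beam);
    y_d need not be monotone in depth near the distal edge.
    """

    points: list[ProfilePoint]
    sf_levels: tuple[float, ...]
    cell_line: Optional[str] = None
    ion: Optional[str] = None

    def __post_init__(self) -> None:
        self.points = sorted(self.points, key=lambda p: p.column_index)

    def _valid(self, sf_level: float) -> list[ProfilePoint]:
        return [
            p
            for p in self.points
            if sf_level in p.estimates and not p.estimates[sf_level].excluded
        ]

    def peak(self, sf_level: float) -> Optional[tuple[float, float, int]]:
        """(y_d, rbe, column) of the profile maximum; ties resolve to the
        lower y_d.  None when fewer than 2 usable points."""
        pts = self._valid(sf_level)
        if len(pts) < 2:
            return None
        best = max(pts, key=lambda p: (p.estimates[sf_level].rbe, -p.y_d))
        return (best.y_d, best.estimates[sf_level].rbe, best.column_index)

    def minimum(self, sf_level: float) -> Optional[tuple[float, float, int]]:
        """(y_d, rbe, column) of the profile minimum (ties to lower y_d)."""
        pts = self._valid(sf_level)
        if len(pts) < 2:
            return None
        best = min(pts, key=lambda p: (p.estimates[sf_level].rbe, p.y_d))
        return (best.y_d, best.estimates[sf_level].rbe, best.column_index)

    def overkill_detected(self, sf_level: float) -> Optional[bool]:
        return detect_overkill(self, sf_level)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table mirroring the published layout: one row per column,
        one (rbe, se, excluded) triple per survival level."""
        records = []
        for p in self.points:
            rec: dict = {"column": p.column_index, "y_d": p.y_d}
            for s in self.sf_levels:
                est = p.estimates.get(s)
                tag = f"sf{s:g}".replace(".", "")
                rec[f"rbe_{tag}"] = est.rbe if est and not est.excluded else None
                rec[f"se_{tag}"] = est.se if est and not est.excluded else None
                rec[f"excluded_{tag}"] = bool(est.excluded) if est else True
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def summary(self) -> dict:
        out: dict = {"cell_line": self.cell_line, "ion": self.ion, "levels": {}}
        for s in self.sf_levels:
            pk, mn = self.peak(s), self.minimum(s)
            out["levels"][f"{s:g}"] = {
                "peak": {"y_d": pk[0], "rbe": pk[1], "column": pk[2]} if pk else None,
                "minimum": {"y_d": mn[0], "rbe": mn[1], "column": mn[2]} if mn else None,
                "overkill_detected": self.overkill_detected(s),
            }
        return out


def detect_overkill(profile: RBEProfile, sf_level: float) -> Optional[bool]:
    """Overkill signature: the RBE maximum sits at a non-final point and at
    least one later point is strictly lower.

    Returns None (undefined, distinct from False) with fewer than 3 usable
    points.  A flat profile or a monotone rise returns False.
    """
    pts = profile._valid(sf_level)
    if len(pts) < 3:
        return None
    values = [p.estimates[sf_level].rbe for p in pts]
    peak_idx = int(np.argmax(values))  # first occurrence: earliest max
    return any(v < values[peak_idx] for v in values[peak_idx + 1 :])


def build_profile(
    fits: Sequence[LQFit],
    reference: LQFit,
    sf_levels: Sequence[float] = (0.5, 0.1),
    cell_line: Optional[str] = None,
    ion: Optional[str] = None,
) -> RBEProfile:
    """Assemble an RBE profile from per-column ion fits and one reference.

    Each fit must carry ``y_d`` metadata (the profile's abscissa) and a
    ``column_index``; exclusions from coverage propagate into the points.
    """
    points = []
    for i, fit in enumerate(fits):
        if fit.y_d is None:
            raise RBEError(f"fit #{i + 1} lacks y_d metadata; profile needs it")
        col = fit.column_index if fit.column_index is not None else i + 1
        estimates = {s: compute_rbe(reference, fit, s) for s in sf_levels}
        points.append(ProfilePoint(column_index=col, y_d=fit.y_d, estimates=estimates))
    return RBEProfile(
        points=points,
        sf_levels=tuple(sf_levels),
        cell_line=cell_line,
        ion=ion or next((f.ion for f in fits if f.ion), None),
    )


def profile_from_table(fixture: TableFixture) -> RBEProfile:
    """Wrap a packaged published RBE table as a profile (no refitting).

    Excluded table entries become excluded estimates; standard errors are
    not printed in the source tables and are carried as unavailable.
    """
    points = []
    for row in fixture.rows:
        estimates = {}
        for level, value in ((0.5, row.rbe_05), (0.1, row.rbe_01)):
            if value is None:
                estimates[level] = RBEEstimate(
                    sf_level=level,
                    rbe=None,
                    se=None,
                    excluded=True,
                    reason="excluded in source table (lack of data coverage)",
                )
            else:
                estimates[level] = RBEEstimate(sf_level=level, rbe=value, se=None)
        points.append(
            ProfilePoint(column_index=row.column_index, y_d=row.y_d, estimates=estimates)
        )
    return RBEProfile(
        points=points,
        sf_levels=(0.5, 0.1),
        cell_line=fixture.cell_line,
        ion=fixture.ion,
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


def fit_columns(
    experiment: PlateExperiment,
    pe: Optional[PlatingEfficiency] = None,
) -> list[LQFit]:
    """Fit one LQ curve per configured column, honouring the detection limit.

    Dose groups whose mean SF falls below the limit of detection are left
    out of the fit (individual wells are never dropped otherwise), and the
    highest retained dose is recorded as the fit's coverage bound.
    """
    if pe is None:
        pe = pool_plating_efficiency(experiment)
    points = surviving_fractions(experiment, pe, include_controls=False)
    usable: dict[int, set[float]] = {}
    covered: dict[int, float] = {}
    for p in points:
        if not p.below_lod:
            usable.setdefault(p.column_index, set()).add(p.dose)
            covered[p.column_index] = max(covered.get(p.column_index, 0.0), p.dose)
    fits = []
    for cond in experiment.conditions:
        col = cond.column_index
        pairs = [
            (d, c)
            for d, c in experiment.column_wells(col)
            if d in usable.get(col, set())
        ]
        if not pairs:
            warnings.warn(
                f"column {col}: no dose group above the detection limit, skipped",
                stacklevel=2,
            )
            continue
        doses, counts = zip(*pairs)
        fits.append(
            fit_lq_poisson(
                doses,
                counts,
                experiment.cells_seeded_per_well,
                pe.pe,
                ion=cond.ion,
                y_d=cond.y_d,
                let_d=cond.let_d,
                column_index=col,
                max_dose_covered=covered[col],
            )
        )
    return fits


def analyze_experiment(
    experiment: PlateExperiment,
    reference: LQFit,
    sf_levels: Sequence[float] = (0.5, 0.1),
    cell_line: Optional[str] = None,
) -> RBEProfile:
    """Full chain: pooled PE -> LOD screening -> per-column Poisson LQ fits
    -> RBE profile against the photon reference."""
    pe = pool_plating_efficiency(experiment)
    fits = fit_columns(experiment, pe)
    return build_profile(fits, reference, sf_levels=sf_levels, cell_line=cell_line)
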