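"""Microdosimetric beam-quality summaries: lineal energy and LET averages.

Lineal energy y is the energy imparted by a single energy-deposition event
in a microscopic site divided by the site's mean chord length; for a convex
sphere of diameter d the mean chord length is exactly 2d/3 (Cauchy).  The
site here is a 2-um diameter sphere emulating a cell nucleus.

Summaries over the single-event spectrum f(y):

    y_f = int y f(y) dy                       frequency-mean
    y_d = int y^2 f(y) dy / int y f(y) dy     dose-mean
    y*  = y_0^2 int (1 - exp(-y^2/y_0^2)) f(y) dy / int y f(y) dy

y* is the saturation-corrected dose-mean lineal energy of the modified
microdosimetric kinetic model: deposits far above the saturation parameter
y_0 (150 keV/um by convention) contribute at a damped weight, encoding the
overkill regime where extra local energy no longer adds lethality.  For a
discrete particle field, dose-averaged LET weights each component's LET by
its dose contribution (proportional to fluence x LET):
LET_d = sum(phi L^2) / sum(phi L).

Spectra may be supplied on a grid (trapezoidal integration, no automatic
re-gridding) or as raw event lists, in which case all moments use exact
sample sums -- never the histogram -- to avoid binning bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

DEFAULT_SITE_DIAMETER_UM = 2.0
DEFAULT_Y0_KEV_UM = 150.0


class MicrodosimetryError(ValueError):
    """Raised for invalid microdosimetric inputs."""


@dataclass(frozen=True)
class SphericalSite:
    """Spherical scoring site; diameter in um."""

    diameter: float = DEFAULT_SITE_DIAMETER_UM

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise MicrodosimetryError(f"site diameter must be positive, got {self.diameter}")

    @property
    def mean_chord_length(self) -> float:
        """Cauchy mean chord length of a convex sphere, 2d/3, in um."""
        return 2.0 * self.diameter / 3.0


def lineal_energy(deposit, site: SphericalSite = SphericalSite()):
    """y = epsilon / mean chord length, keV/um.  ``deposit`` in keV, > 0."""
    eps = np.asarray(deposit, dtype=float)
    if (eps <= 0).any():
        raise MicrodosimetryError("energy deposits must be positive")
    out = eps / site.mean_chord_length
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class EventList:
    """Per-event energy deposits (keV) in one site."""

    deposits: np.ndarray
    site: SphericalSite = SphericalSite()

    def __post_init__(self) -> None:
        arr = np.asarray(self.deposits, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise MicrodosimetryError("need a non-empty 1-D deposit list")
        if (arr <= 0).any():
            raise MicrodosimetryError("all deposits must be positive")
        object.__setattr__(self, "deposits", arr)

    @property
    def lineal_energies(self) -> np.ndarray:
        return self.deposits / self.site.mean_chord_length


@dataclass(frozen=True)
class MicrodosimetricSpectrum:
    """Single-event lineal-energy spectrum: frequency density f on a grid.

    ``sample_y`` optionally carries the raw per-event lineal energies the
    spectrum was histogrammed from; when present, moments use the exact
    sample sums instead of the binned density.
    """

    y: np.ndarray
    f: np.ndarray
    sample_y: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        f = np.asarray(self.f, dtype=float)
        if y.ndim != 1 or y.shape != f.shape or y.size < 2:
            raise MicrodosimetryError("y and f must be matching 1-D arrays (>= 2 points)")
        if (np.diff(y) <= 0).any():
            raise MicrodosimetryError("y grid must be strictly increasing")
        if (f < 0).any():
            raise MicrodosimetryError("frequency density must be non-negative")
        norm = np.trapezoid(f, y)
        if norm <= 0:
            raise MicrodosimetryError("spectrum integrates to zero")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "f", f / norm)
        if self.sample_y is not None:
            object.__setattr__(
                self, "sample_y", np.asarray(self.sample_y, dtype=float)
            )

    # moments -------------------------------------------------------------

    def _moment(self, k: int) -> float:
        if self.sample_y is not None:
            return float(np.mean(self.sample_y**k))
        return float(np.trapezoid(self.y**k * self.f, self.y))

    @property
    def y_f(self) -> float:
        """Frequency-mean lineal energy, keV/um."""
        return self._moment(1)

    @property
    def y_d(self) -> float:
        """Dose-mean lineal energy <y^2>/<y>, keV/um."""
        m1 = self._moment(1)
        if m1 <= 0:
            raise MicrodosimetryError("zero first moment: y_d undefined")
        return self._moment(2) / m1

    def y_star(self, y_0: float = DEFAULT_Y0_KEV_UM) -> float:
        return saturation_corrected_y(self, y_0)

    def dose_density(self) -> np.ndarray:
        """d(y) = y f(y) / int y f dy, the dose-weighted spectrum."""
        m1 = float(np.trapezoid(self.y * self.f, self.y))
        if m1 <= 0:
            raise MicrodosimetryError("zero first moment: dose density undefined")
        return self.y * self.f / m1


def spectrum_from_dose_density(y, d) -> MicrodosimetricSpectrum:
    """Convert a dose density d(y) to canonical frequency form f = d/y."""
    y = np.asarray(y, dtype=float)
    d = np.asarray(d, dtype=float)
    if (y <= 0).any():
        raise MicrodosimetryError("dose-density conversion needs y > 0 everywhere")
    return MicrodosimetricSpectrum(y=y, f=d / y)


def spectrum_from_events(
    events: EventList,
    n_bins: int = 128,
    log_spaced: bool = True,
) -> MicrodosimetricSpectrum:
    """Histogram an event list into a normalized f(y) spectrum.

    The raw lineal energies ride along on the result so its moments stay
    exact (unbinned); the binned density is for plotting and export.
    """
    ys = events.lineal_energies
    lo, hi = ys.min(), ys.max()
    if lo == hi:  # degenerate point spectrum: a narrow box around the value
        lo, hi = lo * 0.999, hi * 1.001
    if log_spaced:
        edges = np.geomspace(lo, hi, n_bins + 1)
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    hist, edges = np.histogram(ys, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return MicrodosimetricSpectrum(y=centers, f=np.maximum(hist, 0), sample_y=ys)


SpectrumLike = Union[MicrodosimetricSpectrum, EventList]


def _as_spectrum_moments(x: SpectrumLike) -> tuple[float, float]:
    """(first, second) raw moments of y, exact for event lists."""
    if isinstance(x, EventList):
        ys = x.lineal_energies
        return float(np.mean(ys)), float(np.mean(ys**2))
    return x._moment(1), x._moment(2)


def frequency_mean_lineal_energy(x: SpectrumLike) -> float:
    """y_f = <y>, keV/um."""
    m1, _ = _as_spectrum_moments(x)
    return m1


def dose_mean_lineal_energy(x: SpectrumLike) -> float:
    """y_d = <y^2>/<y>, keV/um."""
    m1, m2 = _as_spectrum_moments(x)
    if m1 <= 0:
        raise MicrodosimetryError("zero first moment: y_d undefined")
    return m2 / m1


def saturation_corrected_y(x: SpectrumLike, y_0: float = DEFAULT_Y0_KEV_UM) -> float:
    """Saturation-corrected dose-mean lineal energy y*, keV/um.

    y* = y_0^2 <1 - exp(-y^2/y_0^2)> / <y>.  Since 1 - exp(-t) <= t,
    y* <= y_d always, with equality in the y_0 -> infinity limit.
    """
    if y_0 <= 0:
        raise MicrodosimetryError("saturation parameter y_0 must be positive")
    if isinstance(x, EventList):
        ys = x.lineal_energies
        num = y_0**2 * float(np.mean(-np.expm1(-((ys / y_0) ** 2))))
        den = float(np.mean(ys))
    else:
        integrand = -np.expm1(-((x.y / y_0) ** 2)) * x.f
        if x.sample_y is not None:
            ys = x.sample_y
            num = y_0**2 * float(np.mean(-np.expm1(-((ys / y_0) ** 2))))
            den = float(np.mean(ys))
        else:
            num = y_0**2 * float(np.trapezoid(integrand, x.y))
            den = float(np.trapezoid(x.y * x.f, x.y))
    if den <= 0:
        raise MicrodosimetryError("zero first moment: y* undefined")
    return num / den


# ---------------------------------------------------------------------------
# LET averages over a discrete particle field
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FluenceLETTable:
    """Discrete particle field: fluence weights and component LETs (keV/um)."""

    fluence: np.ndarray
    let: np.ndarray

    def __post_init__(self) -> None:
        phi = np.asarray(self.fluence, dtype=float)
        L = np.asarray(self.let, dtype=float)
        if phi.shape != L.shape or phi.ndim != 1 or phi.size == 0:
            raise MicrodosimetryError("fluence and let must be matching 1-D arrays")
        if (phi < 0).any() or phi.sum() == 0:
            raise MicrodosimetryError("fluence weights must be >= 0 and not all zero")
        if (L <= 0).any():
            raise MicrodosimetryError("LET values must be positive")
        object.__setattr__(self, "fluence", phi)
        object.__setattr__(self, "let", L)

    @property
    def let_track(self) -> float:
        """Track (fluence)-averaged LET: sum(phi L) / sum(phi)."""
        return float(np.sum(self.fluence * self.let) / np.sum(self.fluence))

    @property
    def let_dose(self) -> float:
        """Dose-averaged LET: sum(phi L^2) / sum(phi L)."""
        return float(
            np.sum(self.fluence * self.let**2) / np.sum(self.fluence * self.let)
        )


def dose_averaged_let(table: FluenceLETTable) -> float:
    """LET_d = sum(phi L^2) / sum(phi L), keV/um (dose weight ~ phi L)."""
    return table.let_dose


def track_averaged_let(table: FluenceLETTable) -> float:
    """Fluence-averaged LET sum(phi L)/sum(phi), keV/um."""
    return table.let_track
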