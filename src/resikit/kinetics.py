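"""Imaging-duration and stochastic-labelling design calculators.

DNA-PAINT blinking is governed by the imager on-rate ``k_on``, imager
concentration ``c``, mean bright time ``tau_bright`` and camera exposure
``t_exposure``. The mean dark time is ``tau_dark = 1/(k_on * c)``; over a
measurement of duration ``t`` a binding site yields on average

    n_loc = (t / tau_dark) * (tau_bright / t_exposure)

localizations. Inverting gives the acquisition time needed for a requested
RESI precision, since sigma_RESI = sigma_SMLM / sqrt(n_loc).

Stochastic labelling splits one target species over ``n`` orthogonal
sequences with probability 1/n each. Two members of a pair then carry
different sequences with probability 1 - 1/n, and a set of m molecules is
fully resolvable (all sequences distinct) with probability
P(m, n) = n! / ((n - m)! * n^m). For CSR-distributed targets at a given
density, imaging in rounds reduces the effective per-round density to
rho = density / n, and the fraction of targets whose nearest neighbour falls
below the resolvability distance d = 4 * sigma follows the CSR first-NND CDF
F = 1 - exp(-rho * pi * d^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError


@dataclass
class KineticsParams:
    """DNA-PAINT binding kinetics.

    Attributes
    ----------
    k_on
        Imager on-rate, per molar per second (M^-1 s^-1).
    c
        Imager concentration, molar.
    tau_bright
        Mean bright (bound) time, seconds.
    t_exposure
        Camera exposure time, seconds.
    """

    k_on: float
    c: float
    tau_bright: float
    t_exposure: float

    def __post_init__(self) -> None:
        for name in ("k_on", "c", "tau_bright", "t_exposure"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")

    @property
    def tau_dark(self) -> float:
        """Mean dark time between binding events, 1/(k_on * c) seconds."""
        return 1.0 / (self.k_on * self.c)

    @property
    def locs_per_event(self) -> float:
        """Mean localizations per binding event, tau_bright / t_exposure."""
        return self.tau_bright / self.t_exposure


@dataclass
class DesignQuery:
    """Inputs for the stochastic-labelling resolvability calculation.

    ``resolvability_factor`` sets the distance d = factor * sigma_smlm below
    which two targets are considered unresolvable in a single round; the
    default 4 is stricter than the FWHM criterion 2.35 * sigma.
    """

    density: float  # targets per um^2
    sigma_smlm: float  # nm
    n_rounds: int
    resolvability_factor: float = 4.0

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValidationError("density must be >= 0")
        if self.n_rounds < 1:
            raise ValidationError("n_rounds must be >= 1")
        if self.sigma_smlm <= 0 or self.resolvability_factor <= 0:
            raise ValidationError("sigma_smlm and resolvability_factor must be > 0")


def required_localizations(sigma_smlm: float, sigma_resi: float) -> int:
    """Localizations per target needed to reach a requested RESI precision.

    n_loc = ceil((sigma_smlm / sigma_resi)^2), from
    sigma_RESI = sigma_SMLM / sqrt(n_loc). Rounded up: a fractional
    localization cannot be collected.
    """
    if sigma_smlm <= 0 or sigma_resi <= 0:
        raise ValidationError("precisions must be strictly positive")
    if sigma_resi > sigma_smlm:
        raise ValidationError(
            "requested RESI precision exceeds the SMLM precision; no averaging needed"
        )
    ratio = sigma_smlm / sigma_resi
    n = ratio * ratio
    # guard against FP noise pushing an exact square over the next integer
    return int(math.ceil(round(n, 9)))


def measurement_time(k: KineticsParams, n_loc: int) -> float:
    """Mean acquisition time (s) to collect ``n_loc`` localizations per site.

    t = (t_exposure * n_loc) / (tau_bright * k_on * c).
    """
    if n_loc < 1:
        raise ValidationError("n_loc must be >= 1")
    return (k.t_exposure * n_loc) / (k.tau_bright * k.k_on * k.c)


def expected_locs(k: KineticsParams, t_measurement: float) -> float:
    """Mean number of localizations per site collected in ``t_measurement`` s.

    Algebraic inverse of :func:`measurement_time`:
    n = t * k_on * c * tau_bright / t_exposure.
    """
    return t_measurement * k.k_on * k.c * k.tau_bright / k.t_exposure


def p_pair_distinct(n_rounds: int) -> float:
    """Probability that both members of a pair receive different sequences.

    P(diff. seq.) = 1 - 1/n for uniform stochastic labelling over n sequences.
    """
    if n_rounds < 1:
        raise ValidationError("n_rounds must be >= 1")
    return 1.0 - 1.0 / n_rounds


def p_all_distinct(m: int, n_rounds: int) -> float:
    """Probability that m molecules all receive distinct sequences out of n.

    P(m, n) = n! / ((n - m)! * n^m) for m <= n, and 0 for m > n.
    """
    if m < 1:
        raise ValidationError("m must be >= 1")
    if n_rounds < 1:
        raise ValidationError("n_rounds must be >= 1")
    n = n_rounds
    if m > n:
        return 0.0
    return math.perm(n, m) / n**m


def unresolved_fraction(
    query: DesignQuery,
    method: str = "closed_form",
    seed: int | None = None,
    n_points: int = 100_000,
) -> float:
    """Fraction F of targets not resolvable in a single imaging round.

    The effective per-round density under n-round stochastic labelling is
    rho = density / n_rounds. Two CSR targets closer than
    d = resolvability_factor * sigma_smlm are unresolvable, so F is the CSR
    first-NND CDF at d:

        F = 1 - exp(-rho * pi * d^2)

    ``method="simulation"`` instead draws a CSR pattern at density rho and
    counts the fraction of first nearest-neighbour distances below d
    (guard-band edge handling); it converges to the closed form.
    """
    if query.density == 0:
        return 0.0
    rho_um2 = query.density / query.n_rounds
    d = query.resolvability_factor * query.sigma_smlm  # nm
    rho_nm2 = rho_um2 * 1e-6
    if method == "closed_form":
        return 1.0 - math.exp(-rho_nm2 * math.pi * d * d)
    if method == "simulation":
        from scipy.spatial import cKDTree

        rng = np.random.default_rng(seed)
        area_um2 = n_points / rho_um2
        side = math.sqrt(area_um2) * 1000.0  # nm
        guard = max(10.0 * d, 100.0)
        n_all = rng.poisson(rho_nm2 * (side + 2 * guard) ** 2)
        pts = rng.uniform(-guard, side + guard, size=(n_all, 2))
        core = np.all((pts >= 0) & (pts <= side), axis=1)
        if core.sum() < 2:
            return 0.0
        tree = cKDTree(pts)
        dist, _ = tree.query(pts[core], k=2)
        return float(np.mean(dist[:, 1] < d))
    raise ValidationError(f"unknown method {method!r}")


def design_table(
    densities: "np.ndarray | list[float]",
    n_rounds_list: "list[int]",
    sigma_smlm: float,
    resolvability_factor: float = 4.0,
):
    """Closed-form F over a grid of densities and round counts.

    Returns a pandas DataFrame with one row per density and one column per
    round count -- the design map used to choose the number of orthogonal
    sequences for a given target density and SMLM resolution.
    """
    import pandas as pd

    rows = {}
    for n in n_rounds_list:
        rows[f"n={n}"] = [
            unresolved_fraction(
                DesignQuery(d, sigma_smlm, n, resolvability_factor), "closed_form"
            )
            for d in densities
        ]
    return pd.DataFrame(rows, index=pd.Index(densities, name="density_per_um2"))
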