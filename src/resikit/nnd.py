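"""Nearest-neighbour distance analysis and the monomer/dimer mixture fit.

Membrane-receptor organization is inferred from k-th nearest-neighbour
distance (NND) statistics of the detected molecule positions. Under complete
spatial randomness (CSR) at intensity rho, the first-NND CDF is
``1 - exp(-rho * pi * d^2)``; deviations at short range reveal oligomers.

The dimer fit asks: what mixture of CSR monomers and CSR-centred dimers best
reproduces the observed first-NND histogram? The generative model (shared
with :mod:`resikit.synth`, so fit and simulation are self-consistent) has
three free parameters:

* ``D`` — mean intra-dimer molecule distance (nm),
* ``sigma_label`` — per-molecule positional variability from labelling and
  localization (nm),
* ``frac_of_dimers`` — percentage of molecules belonging to dimers
  (``frac_of_monomers = 100 - frac_of_dimers``).

The observed molecule density and the labelling efficiency are fixed to
their experimental values; the ground-truth density is
``observed_density / labelling_efficiency`` so simulated detectable density
matches the data by construction. Fitting is iterative nonlinear least
squares on the binned NND histogram: a coarse grid over D = 1-20 nm,
sigma_label = 1-20 nm, frac = 0-100 %, then Nelder-Mead refinement of the
simulation-based objective (replicate simulations averaged, common random
numbers across evaluations to smooth the stochastic objective). Parameter
uncertainties come from refitting M simulated datasets drawn at the optimum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.spatial import cKDTree

from .errors import ValidationError
from .synth import GUARD_BAND_NM, mixture_from_fit_params, simulate_mixture

#: default SSE histogram binning: 1 nm bins over 0-100 nm
DEFAULT_BIN_EDGES = np.arange(0.0, 101.0, 1.0)

#: coarse-fit parameter ranges: D (nm), sigma_label (nm), frac_of_dimers (%)
COARSE_RANGES = ((1.0, 20.0), (1.0, 20.0), (0.0, 100.0))


@dataclass
class NndResult:
    """k-th nearest-neighbour distances of a 2D point set.

    ``distances[k]`` (for k in ``orders``, 1-based) is the array of k-th NN
    Euclidean distances in nm, one per point.
    """

    orders: list[int]
    distances: dict[int, np.ndarray]
    density_observed: float  # points per um^2
    bin_edges: np.ndarray | None = None

    def histogram(self, order: int = 1, bin_edges: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Normalized (fraction per bin) histogram of the given NND order."""
        edges = bin_edges if bin_edges is not None else (
            self.bin_edges if self.bin_edges is not None else DEFAULT_BIN_EDGES
        )
        d = self.distances[order]
        counts, edges = np.histogram(d, bins=edges)
        return counts / max(len(d), 1), edges


@dataclass
class DimerFitResult:
    """Best-fit monomer/dimer mixture parameters.

    ``uncertainties`` holds the per-parameter s.d. across refits once
    :func:`fit_uncertainty` has run (keys ``D``, ``sigma_label``,
    ``frac_of_dimers``).
    """

    D_opt: float
    sigma_label_opt: float
    frac_of_dimers_opt: float
    sse: float
    observed_density: float
    labelling_efficiency: float
    n_molecules: int
    uncertainties: dict = field(default_factory=dict)
    n_refits: int = 0
    low_m_flag: bool = False
    failed: bool = False


def knn_distances(points: np.ndarray, max_order: int = 4) -> NndResult:
    """Exact k-th nearest-neighbour distances for k = 1..max_order."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(points)
    if n <= max_order:
        raise ValidationError(f"need more than {max_order} points, got {n}")
    tree = cKDTree(points)
    dist, _ = tree.query(points, k=max_order + 1)
    extent = points.max(axis=0) - points.min(axis=0)
    area_um2 = float(np.prod(np.maximum(extent, 1.0))) / 1e6
    return NndResult(
        orders=list(range(1, max_order + 1)),
        distances={k: dist[:, k] for k in range(1, max_order + 1)},
        density_observed=n / area_um2,
    )


def csr_reference(
    density: float,
    area: float,
    orders: int = 4,
    seed: int | None = None,
) -> NndResult:
    """Simulated CSR NND distributions at a given density.

    ``density`` in points per um^2, ``area`` in um^2. Points are generated in
    a window enlarged by a 100 nm guard band; distances are reported for core
    points only but computed against all points, so there is no edge
    deflation.
    """
    if density <= 0:
        raise ValidationError("density must be > 0")
    if area <= 0:
        raise ValidationError("area must be > 0")
    rng = np.random.default_rng(seed)
    side = math.sqrt(area) * 1000.0
    g = GUARD_BAND_NM
    full_area_um2 = ((side + 2 * g) / 1000.0) ** 2
    n = rng.poisson(density * full_area_um2)
    pts = rng.uniform(-g, side + g, size=(n, 2))
    core = np.all((pts >= 0) & (pts <= side), axis=1)
    if core.sum() <= orders:
        raise ValidationError("too few points for the requested NND orders")
    tree = cKDTree(pts)
    dist, _ = tree.query(pts[core], k=orders + 1)
    return NndResult(
        orders=list(range(1, orders + 1)),
        distances={k: dist[:, k] for k in range(1, orders + 1)},
        density_observed=core.sum() / area,
    )


def csr_nnd_cdf(d, density: float) -> np.ndarray:
    """Closed-form CSR first-NND CDF, 1 - exp(-rho*pi*d^2); d nm, density per um^2."""
    rho_nm2 = density * 1e-6
    return 1.0 - np.exp(-rho_nm2 * math.pi * np.square(np.asarray(d, dtype=float)))


def sse_histogram(sim_distances, exp_distances, bin_edges=DEFAULT_BIN_EDGES) -> float:
    """Sum of squared differences between normalized NND histograms.

    Histograms are normalized to fractions of their totals so samples of
    different sizes are comparable.
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges.ndim != 1 or len(bin_edges) < 2:
        raise ValidationError("bin_edges must be a 1D array of >= 2 edges")
    sim = np.asarray(sim_distances, dtype=float)
    exp = np.asarray(exp_distances, dtype=float)
    h_sim, _ = np.histogram(sim, bins=bin_edges)
    h_exp, _ = np.histogram(exp, bins=bin_edges)
    f_sim = h_sim / max(len(sim), 1)
    f_exp = h_exp / max(len(exp), 1)
    return float(np.sum((f_sim - f_exp) ** 2))


# ---------------------------------------------------------------------------
# mixture fit
# ---------------------------------------------------------------------------


def _first_nnd(points: np.ndarray) -> np.ndarray:
    tree = cKDTree(points)
    dist, _ = tree.query(points, k=2)
    return dist[:, 1]


def _objective(
    params3: tuple[float, float, float],
    exp_hist: np.ndarray,
    observed_density: float,
    labelling_efficiency: float,
    area: float,
    bin_edges: np.ndarray,
    seeds: np.ndarray,
) -> float:
    """SSE between the experimental histogram and the replicate-averaged
    simulated histogram at one parameter triple.

    Averaging the simulated histograms before squaring (rather than
    averaging per-replicate SSEs) shrinks the simulation shot-noise floor of
    the objective by the replicate count, which matters because competing
    parameter basins can differ by less than the single-replicate noise.
    """
    d_nm, sigma, frac = params3
    mp = mixture_from_fit_params(
        d_nm, sigma, frac, observed_density, labelling_efficiency, area
    )
    acc = np.zeros(len(bin_edges) - 1)
    for s in seeds:
        pts = simulate_mixture(mp, seed=int(s))
        if len(pts) < 2:
            return float("inf")
        h, _ = np.histogram(_first_nnd(pts), bins=bin_edges)
        acc += h / len(pts)
    return float(np.sum((acc / len(seeds) - exp_hist) ** 2))


def fit_dimer_model(
    exp_points: "np.ndarray | NndResult",
    observed_density: float,
    labelling_efficiency: float,
    seed: int | None = None,
    bin_edges: np.ndarray = DEFAULT_BIN_EDGES,
    coarse_steps: tuple[int, int, int] = (11, 11, 11),
    n_replicates: int = 4,
    coarse_n_molecules: int = 5000,
    n_rerank: int = 20,
    rerank_replicates: int = 4,
    maxiter: int = 120,
) -> DimerFitResult:
    """Iterative nonlinear least-squares fit of the monomer/dimer model.

    Parameters
    ----------
    exp_points
        (N, 2) nm point set of detected molecules, or a precomputed
        :class:`NndResult` whose order-1 distances are used.
    observed_density
        Detected molecules per um^2; must match the data.
    labelling_efficiency
        Detectable fraction in (0, 1].
    seed
        Seeds the common random numbers used across objective evaluations.

    The coarse stage evaluates the SSE objective on a grid over
    D = 1-20 nm, sigma_label = 1-20 nm, frac = 0-100 % (simulating a reduced
    window of ~``coarse_n_molecules`` detectable molecules, since histogram
    shape depends on density rather than count); the ``n_rerank`` best grid
    points are then re-evaluated at the data-matched window size with
    ``rerank_replicates`` replicate simulations to pick the start of the fine
    stage -- this guards against the cheap coarse pass selecting a spurious
    basin within its noise floor. The fine stage runs Nelder-Mead from that
    start at the data-matched window size, averaging ``n_replicates``
    simulated histograms per evaluation (common random numbers throughout).
    """
    if not 0.0 < labelling_efficiency <= 1.0:
        raise ValidationError("labelling_efficiency must be in (0, 1]")
    if observed_density <= 0:
        raise ValidationError("observed_density must be > 0")
    if isinstance(exp_points, NndResult):
        exp_d = exp_points.distances[1]
        n_molecules = len(exp_d)
    else:
        pts = np.atleast_2d(np.asarray(exp_points, dtype=float))
        if len(pts) < 10:
            raise ValidationError("too few points to fit")
        if np.allclose(pts.std(axis=0), 0.0):
            return DimerFitResult(
                float("nan"), float("nan"), float("nan"), float("inf"),
                observed_density, labelling_efficiency, len(pts), failed=True,
            )
        exp_d = _first_nnd(pts)
        n_molecules = len(pts)

    bin_edges = np.asarray(bin_edges, dtype=float)
    h_exp, _ = np.histogram(exp_d, bins=bin_edges)
    exp_hist = h_exp / len(exp_d)

    rng = np.random.default_rng(seed)
    # common random numbers: the same simulation seeds for every evaluation
    coarse_seeds = rng.integers(0, 2**31 - 1, size=1)
    fine_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)

    area_data = n_molecules / observed_density  # um^2
    area_coarse = min(coarse_n_molecules / observed_density, area_data)

    (d_lo, d_hi), (s_lo, s_hi), (f_lo, f_hi) = COARSE_RANGES
    grid_d = np.linspace(d_lo, d_hi, coarse_steps[0])
    grid_s = np.linspace(s_lo, s_hi, coarse_steps[1])
    grid_f = np.linspace(f_lo, f_hi, coarse_steps[2])
    scored: list[tuple[float, tuple[float, float, float]]] = []
    for dv in grid_d:
        for sv in grid_s:
            for fv in grid_f:
                val = _objective(
                    (dv, sv, fv), exp_hist, observed_density,
                    labelling_efficiency, area_coarse, bin_edges, coarse_seeds,
                )
                scored.append((val, (dv, sv, fv)))
    scored.sort(key=lambda t: t[0])
    # re-rank the best coarse candidates with a lower-noise objective
    rerank_seeds = rng.integers(0, 2**31 - 1, size=rerank_replicates)
    best = min(
        scored[: max(n_rerank, 1)],
        key=lambda t: _objective(
            t[1], exp_hist, observed_density, labelling_efficiency,
            area_data, bin_edges, rerank_seeds,
        ),
    )
    x0 = np.asarray(best[1], dtype=float)

    lo = np.array([d_lo, s_lo, f_lo])
    hi = np.array([d_hi, s_hi, f_hi])

    def clipped_objective(x):
        xc = np.clip(x, lo, hi)
        penalty = float(np.sum((x - xc) ** 2)) * 1e-3
        return _objective(
            tuple(xc), exp_hist, observed_density, labelling_efficiency,
            area_data, bin_edges, fine_seeds,
        ) + penalty

    res = optimize.minimize(
        clipped_objective,
        x0,
        method="Nelder-Mead",
        options={
            "maxiter": maxiter,
            "xatol": 0.05,
            "fatol": 1e-7,
            "initial_simplex": _initial_simplex(x0, lo, hi),
        },
    )
    d_opt, s_opt, f_opt = np.clip(res.x, lo, hi)
    return DimerFitResult(
        D_opt=float(d_opt),
        sigma_label_opt=float(s_opt),
        frac_of_dimers_opt=float(f_opt),
        sse=float(res.fun),
        observed_density=observed_density,
        labelling_efficiency=labelling_efficiency,
        n_molecules=n_molecules,
    )


def _initial_simplex(x0: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Simplex spanning roughly one coarse-grid cell around the start."""
    steps = np.array([1.5, 1.5, 8.0])
    simplex = [x0]
    for i in range(3):
        v = x0.copy()
        v[i] = v[i] + steps[i] if v[i] + steps[i] <= hi[i] else v[i] - steps[i]
        simplex.append(v)
    return np.clip(np.asarray(simplex), lo, hi)


def fit_uncertainty(
    fit: DimerFitResult,
    n_molecules: int | None = None,
    M: int = 100,
    seed: int | None = None,
    n_replicates: int = 3,
    maxiter: int = 80,
) -> DimerFitResult:
    """Refit-based parameter uncertainties.

    Simulates ``M`` synthetic datasets at the fitted optimum with
    ``n_molecules`` detectable molecules each (default: the size of the
    fitted data), fine-fits each (Nelder-Mead from the optimum, skipping the
    coarse grid), and stores the per-parameter standard deviation across
    refits in ``fit.uncertainties``.
    """
    if M < 2:
        raise ValidationError("M must be >= 2")
    if fit.failed:
        raise ValidationError("cannot bootstrap a failed fit")
    n_molecules = n_molecules or fit.n_molecules
    rng = np.random.default_rng(seed)
    area = n_molecules / fit.observed_density
    mp = mixture_from_fit_params(
        fit.D_opt, fit.sigma_label_opt, fit.frac_of_dimers_opt,
        fit.observed_density, fit.labelling_efficiency, area,
    )
    lo = np.array([COARSE_RANGES[0][0], COARSE_RANGES[1][0], COARSE_RANGES[2][0]])
    hi = np.array([COARSE_RANGES[0][1], COARSE_RANGES[1][1], COARSE_RANGES[2][1]])
    x_opt = np.array([fit.D_opt, fit.sigma_label_opt, fit.frac_of_dimers_opt])
    bin_edges = DEFAULT_BIN_EDGES
    results = []
    for _ in range(M):
        pts = simulate_mixture(mp, seed=int(rng.integers(0, 2**31 - 1)))
        exp_d = _first_nnd(pts)
        h, _ = np.histogram(exp_d, bins=bin_edges)
        exp_hist = h / len(pts)
        fine_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)

        def obj(x, _h=exp_hist, _s=fine_seeds, _n=len(pts)):
            xc = np.clip(x, lo, hi)
            return _objective(
                tuple(xc), _h, fit.observed_density, fit.labelling_efficiency,
                _n / fit.observed_density, bin_edges, _s,
            ) + float(np.sum((x - xc) ** 2)) * 1e-3

        res = optimize.minimize(
            obj, x_opt, method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 0.05, "fatol": 1e-7,
                     "initial_simplex": _initial_simplex(x_opt, lo, hi)},
        )
        results.append(np.clip(res.x, lo, hi))
    arr = np.asarray(results)
    sd = arr.std(axis=0, ddof=1)
    fit.uncertainties = {
        "D": float(sd[0]),
        "sigma_label": float(sd[1]),
        "frac_of_dimers": float(sd[2]),
    }
    fit.n_refits = M
    fit.low_m_flag = M < 10
    if fit.low_m_flag:
        warnings.warn(f"uncertainties from only M={M} refits; treat as indicative")
    return fit
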