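"""Synthetic ground-truth layouts and DNA-PAINT localization tables.

Every downstream stage of the toolkit is testable offline against data from
this module. It emulates the statistical structure of sequential DNA-PAINT
(Exchange-PAINT) acquisitions:

* ground-truth binding-site layouts (grids, closely spaced site pairs,
  eight-fold-symmetric ring complexes resembling the nuclear pore, and CSR
  point patterns at a given density);
* stochastic assignment of sites to ``n`` orthogonal sequence channels with
  probability 1/n each;
* localization clouds: isotropic Gaussian scatter of s.d. ``sigma_smlm``
  around each site (axial s.d. defaults to twice the lateral, matching the
  roughly twofold larger z spread of astigmatic 3D detection), with frame
  indices drawn from a blinking model and per-localization precision
  ``lp = sigma_smlm``;
* sticking-event artifacts: spurious clusters whose frames are compressed
  into a short consecutive span, injected at random positions;
* membrane-receptor monomer/dimer mixtures with labelling-efficiency
  thinning, the generative model behind the nearest-neighbour dimer fit.

All generators are deterministic given (seed, parameters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import AcquisitionMeta, LocalizationTable
from .kinetics import KineticsParams

#: guard band (nm) around CSR windows, to avoid nearest-neighbour edge bias
GUARD_BAND_NM = 100.0


@dataclass
class GroundTruthLayout:
    """Simulated binding-site positions with channel assignments.

    ``sites`` is an (N, 2) or (N, 3) array of nm coordinates;
    ``channel_of_site`` holds one integer label in ``[0, n_rounds)`` per site.
    """

    sites: np.ndarray
    channel_of_site: np.ndarray
    n_rounds: int = 1

    def __post_init__(self) -> None:
        self.sites = np.atleast_2d(np.asarray(self.sites, dtype=float))
        if self.sites.size == 0:
            self.sites = self.sites.reshape(0, 2)
        self.channel_of_site = np.asarray(self.channel_of_site, dtype=int)
        if not np.all(np.isfinite(self.sites)):
            raise ValidationError("site coordinates must be finite")
        if len(self.channel_of_site) != len(self.sites):
            raise ValidationError("one channel label per site required")
        if self.n_rounds < 1:
            raise ValidationError("n_rounds must be >= 1")
        if len(self.channel_of_site) and (
            self.channel_of_site.min() < 0 or self.channel_of_site.max() >= self.n_rounds
        ):
            raise ValidationError("channel labels must lie in [0, n_rounds)")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def is_3d(self) -> bool:
        return self.sites.shape[1] == 3

    def to_frame(self) -> pd.DataFrame:
        cols = ["x", "y", "z"][: self.sites.shape[1]]
        df = pd.DataFrame(self.sites, columns=cols)
        df["channel"] = self.channel_of_site
        return df


@dataclass
class BlinkModel:
    """How localization frame indices are generated.

    ``uniform_frames`` draws i.i.d. uniform frames over the acquisition --
    the idealization of repetitive blinking whose cluster mean frame centres
    at half the total frame count. ``kinetic`` simulates binding events as a
    Poisson process of rate ``k_on * c`` with ``tau_bright / t_exposure``
    consecutive localizations per event (stochastically rounded).

    ``sticking_fraction`` is the probability, per true site, of injecting one
    spurious cluster (at a random position, not on a site) whose frames all
    fall within ``sticking_span`` consecutive frames -- emulating unspecific
    sticking of imagers.
    """

    mode: str = "uniform_frames"
    kinetics: KineticsParams | None = None
    sticking_fraction: float = 0.0
    sticking_span: int = 100

    def __post_init__(self) -> None:
        if self.mode not in ("uniform_frames", "kinetic"):
            raise ValidationError(f"unknown blink mode {self.mode!r}")
        if self.mode == "kinetic" and self.kinetics is None:
            raise ValidationError("kinetic mode requires KineticsParams")
        if not 0.0 <= self.sticking_fraction <= 1.0:
            raise ValidationError("sticking_fraction must be in [0, 1]")
        if self.sticking_span < 1:
            raise ValidationError("sticking_span must be >= 1")


@dataclass
class MixtureParams:
    """Parameters of the CSR monomer/dimer membrane-receptor model.

    ``density_monomers`` counts monomeric molecules per um^2 and
    ``density_dimers`` counts dimers (pairs) per um^2, each contributing two
    molecules. Each dimer's two molecules sit at a fixed distance
    ``dimer_distance`` (nm) apart in a uniformly random orientation about a
    CSR-distributed centre. Every molecule position is perturbed by an
    isotropic Gaussian of s.d. ``uncertainty`` (nm, labelling + localization
    variability) and survives detection independently with probability
    ``labelling_efficiency``.
    """

    density_monomers: float = 0.0  # per um^2
    density_dimers: float = 0.0  # dimer pairs per um^2
    dimer_distance: float = 0.0  # nm
    uncertainty: float = 0.0  # nm
    labelling_efficiency: float = 1.0
    area: float = 100.0  # um^2

    def __post_init__(self) -> None:
        if self.density_monomers < 0 or self.density_dimers < 0:
            raise ValidationError("densities must be >= 0")
        if not 0.0 <= self.labelling_efficiency <= 1.0:
            raise ValidationError("labelling_efficiency must be in [0, 1]")
        if self.dimer_distance < 0 or self.uncertainty < 0:
            raise ValidationError("dimer_distance and uncertainty must be >= 0")
        if self.area <= 0:
            raise ValidationError("area must be > 0")


# ---------------------------------------------------------------------------
# layouts
# ---------------------------------------------------------------------------


def make_layout(kind: str, seed: int | None = None, **params) -> GroundTruthLayout:
    """Generate a ground-truth site layout.

    Kinds
    -----
    ``grid``
        Rectangular grid: ``nx``, ``ny`` sites at spacing ``pitch`` (nm).
    ``pair_grid``
        ``n_pairs`` site pairs on a grid of spacing ``pitch`` (default 6
        pairs on a 20 nm grid), each pair split by ``pair_offset`` nm along
        x -- the flat-origami geometry used to probe sub-nm separations.
    ``ring_complex``
        Two axially separated rings (separation ``ring_separation`` nm) of
        ``n_fold``-fold symmetric site pairs at ring radius ``radius`` nm;
        pair members are split by ``pair_lateral`` nm tangentially and
        ``pair_axial`` nm axially. Defaults mimic the Nup96 arrangement in
        the nuclear pore (8 pairs per ring, 11.9 nm lateral / 5.4 nm axial
        splitting). 3D.
    ``csr``
        Homogeneous Poisson pattern: ``density`` per um^2 over ``area`` um^2;
        the site count is Poisson(density * area).
    """
    if kind == "grid":
        return _grid_layout(**params)
    if kind == "pair_grid":
        return _pair_grid_layout(**params)
    if kind == "ring_complex":
        return _ring_complex_layout(**params)
    if kind == "csr":
        return _csr_layout(seed=seed, **params)
    raise ValidationError(f"unknown layout kind {kind!r}")


def _grid_layout(nx: int = 4, ny: int = 4, pitch: float = 20.0) -> GroundTruthLayout:
    if pitch <= 0 or nx < 1 or ny < 1:
        raise ValidationError("grid requires positive pitch and counts")
    gx, gy = np.meshgrid(np.arange(nx) * pitch, np.arange(ny) * pitch)
    sites = np.column_stack([gx.ravel(), gy.ravel()])
    return GroundTruthLayout(sites, np.zeros(len(sites), dtype=int))


def _pair_grid_layout(
    n_pairs: int = 6, pitch: float = 20.0, pair_offset: float = 0.7
) -> GroundTruthLayout:
    if pitch <= 0 or pair_offset < 0 or n_pairs < 1:
        raise ValidationError("pair_grid requires positive pitch and offset >= 0")
    ncols = int(math.ceil(math.sqrt(n_pairs)))
    centres = []
    for i in range(n_pairs):
        centres.append(((i % ncols) * pitch, (i // ncols) * pitch))
    centres = np.asarray(centres, dtype=float)
    half = np.array([pair_offset / 2.0, 0.0])
    sites = np.concatenate([centres - half, centres + half])
    # interleave so that pair k occupies rows (2k, 2k+1)
    order = np.ravel(np.column_stack([np.arange(n_pairs), np.arange(n_pairs) + n_pairs]))
    return GroundTruthLayout(sites[order], np.zeros(2 * n_pairs, dtype=int))


def _ring_complex_layout(
    n_fold: int = 8,
    radius: float = 55.0,
    pair_lateral: float = 11.9,
    pair_axial: float = 5.4,
    ring_separation: float = 50.0,
) -> GroundTruthLayout:
    if n_fold < 1 or radius <= 0:
        raise ValidationError("ring_complex requires n_fold >= 1 and radius > 0")
    if pair_lateral > 2.0 * radius:
        raise ValidationError("pair_lateral cannot exceed the ring diameter")
    sites = []
    # half-angle chosen so the chord between pair members is exactly
    # pair_lateral in the ring plane
    half_angle = math.asin(pair_lateral / (2.0 * radius))
    for z0 in (-ring_separation / 2.0, ring_separation / 2.0):
        for k in range(n_fold):
            phi = 2.0 * math.pi * k / n_fold
            for s in (-1.0, 1.0):
                a = phi + s * half_angle
                sites.append(
                    (radius * math.cos(a), radius * math.sin(a), z0 + s * pair_axial / 2.0)
                )
    sites = np.asarray(sites)
    return GroundTruthLayout(sites, np.zeros(len(sites), dtype=int))


def _csr_layout(
    density: float = 100.0, area: float = 100.0, seed: int | None = None
) -> GroundTruthLayout:
    if density < 0:
        raise ValidationError("density must be >= 0")
    if area <= 0:
        raise ValidationError("area must be > 0")
    rng = np.random.default_rng(seed)
    side = math.sqrt(area) * 1000.0  # nm
    n = rng.poisson(density * area)
    sites = rng.uniform(0.0, side, size=(n, 2))
    return GroundTruthLayout(sites, np.zeros(n, dtype=int))


def assign_channels(
    layout: GroundTruthLayout, n_rounds: int, seed: int | None = None
) -> GroundTruthLayout:
    """Assign each site an i.i.d. uniform channel in ``[0, n_rounds)``.

    Models stochastic labelling with ``n_rounds`` orthogonal sequences at
    equal probability 1/n per sequence.
    """
    if n_rounds < 1:
        raise ValidationError("n_rounds must be >= 1")
    rng = np.random.default_rng(seed)
    channels = rng.integers(0, n_rounds, size=layout.n_sites)
    return replace(layout, channel_of_site=channels, n_rounds=n_rounds)


# ---------------------------------------------------------------------------
# localization sampling
# ---------------------------------------------------------------------------


def _frames_for_site(k: int, blink: BlinkModel, n_frames: int, rng) -> np.ndarray:
    if blink.mode == "uniform_frames":
        return rng.integers(0, n_frames, size=k)
    # kinetic mode: events at uniform start frames, consecutive frames per event
    kin = blink.kinetics
    locs_per_event = kin.locs_per_event
    frames: list[int] = []
    while len(frames) < k:
        start = int(rng.integers(0, n_frames))
        n_ev = int(math.floor(locs_per_event) + (rng.random() < locs_per_event % 1.0))
        n_ev = max(n_ev, 1)
        frames.extend(range(start, min(start + n_ev, n_frames)))
    return np.asarray(frames[:k], dtype=np.int64)


def _kinetic_count(kin: KineticsParams, n_frames: int, rng) -> int:
    t_total = n_frames * kin.t_exposure
    n_events = rng.poisson(t_total * kin.k_on * kin.c)
    mean_locs = kin.locs_per_event
    k = 0
    for _ in range(n_events):
        k += int(math.floor(mean_locs) + (rng.random() < mean_locs % 1.0))
    return k


def sample_localizations(
    layout: GroundTruthLayout,
    sigma_smlm: float,
    locs_per_site: "int | KineticsParams" = 100,
    sigma_z: float | None = None,
    blink: BlinkModel | None = None,
    meta: AcquisitionMeta | None = None,
    seed: int | None = None,
) -> list[LocalizationTable]:
    """Simulate one localization table per channel from a layout.

    Each site emits ``K`` localizations scattered isotropically around it
    with lateral s.d. ``sigma_smlm`` (axial s.d. ``sigma_z``, default
    ``2 * sigma_smlm``, for 3D layouts); every localization carries
    ``lp = sigma_smlm``. ``locs_per_site`` may be a fixed integer or
    :class:`~resikit.kinetics.KineticsParams`, in which case the count is
    drawn from the binding-kinetics model. Frame indices follow ``blink``.

    Returns a list of ``layout.n_rounds`` tables (possibly empty), one per
    channel.
    """
    if sigma_smlm <= 0:
        raise ValidationError("sigma_smlm must be > 0")
    blink = blink or BlinkModel()
    rng = np.random.default_rng(seed)
    is_3d = layout.is_3d
    if sigma_z is None:
        sigma_z = 2.0 * sigma_smlm
    if meta is None:
        if layout.n_sites:
            w = float(layout.sites[:, 0].max() - min(layout.sites[:, 0].min(), 0.0))
            h = float(layout.sites[:, 1].max() - min(layout.sites[:, 1].min(), 0.0))
        else:
            w = h = 1000.0
        meta = AcquisitionMeta(
            n_frames=10_000,
            field_width=max(w, 1.0),
            field_height=max(h, 1.0),
            is_3d=is_3d,
        )
    n_frames = meta.n_frames

    rows = {ch: [] for ch in range(layout.n_rounds)}
    for idx in range(layout.n_sites):
        site = layout.sites[idx]
        ch = int(layout.channel_of_site[idx])
        if isinstance(locs_per_site, KineticsParams):
            k = _kinetic_count(locs_per_site, n_frames, rng)
        else:
            k = int(locs_per_site)
        if k == 0:
            continue
        xy = site[:2] + rng.normal(0.0, sigma_smlm, size=(k, 2))
        frames = _frames_for_site(k, blink, n_frames, rng)
        rec = {"frame": frames, "x": xy[:, 0], "y": xy[:, 1]}
        if is_3d:
            rec["z"] = site[2] + rng.normal(0.0, sigma_z, size=k)
        rows[ch].append(pd.DataFrame(rec))

    # sticking artifacts: spurious clusters at random positions whose frames
    # are confined to a short consecutive window
    if blink.sticking_fraction > 0 and layout.n_sites:
        n_art = rng.binomial(layout.n_sites, blink.sticking_fraction)
        lo = layout.sites.min(axis=0)
        hi = layout.sites.max(axis=0)
        span = np.maximum(hi - lo, 1.0)
        for _ in range(n_art):
            ch = int(rng.integers(0, layout.n_rounds))
            k = int(locs_per_site) if not isinstance(locs_per_site, KineticsParams) else max(
                _kinetic_count(locs_per_site, n_frames, rng), 1
            )
            pos = lo + rng.uniform(0.0, 1.0, size=lo.shape) * span
            xy = pos[:2] + rng.normal(0.0, sigma_smlm, size=(k, 2))
            start = int(rng.integers(0, max(n_frames - blink.sticking_span, 1)))
            frames = rng.integers(start, min(start + blink.sticking_span, n_frames), size=k)
            rec = {"frame": frames, "x": xy[:, 0], "y": xy[:, 1]}
            if is_3d:
                rec["z"] = pos[2] + rng.normal(0.0, sigma_z, size=k)
            rows[ch].append(pd.DataFrame(rec))

    tables = []
    cols = ["frame", "x", "y"] + (["z"] if is_3d else [])
    for ch in range(layout.n_rounds):
        if rows[ch]:
            df = pd.concat(rows[ch], ignore_index=True)
        else:
            df = pd.DataFrame({c: pd.Series(dtype=float) for c in cols})
            df["frame"] = df.get("frame", pd.Series(dtype=np.int64)).astype(np.int64)
        df["lp"] = sigma_smlm
        df["channel"] = ch
        tables.append(LocalizationTable(df, replace(meta, is_3d=is_3d)))
    return tables


# ---------------------------------------------------------------------------
# monomer/dimer mixtures
# ---------------------------------------------------------------------------


def simulate_mixture(
    params: MixtureParams,
    seed: int | None = None,
    return_labels: bool = False,
):
    """Draw the detectable-molecule point set of a CSR monomer/dimer mixture.

    Monomers and dimer centres are homogeneous Poisson patterns at their
    respective densities; each dimer contributes two molecules at distance
    ``dimer_distance`` in a uniformly random orientation. Every molecule is
    perturbed by an isotropic Gaussian of s.d. ``uncertainty`` and kept
    independently with probability ``labelling_efficiency``. Points are
    generated in a window enlarged by a 100 nm guard band and cropped to the
    core window afterwards, so nearest-neighbour statistics near the window
    edge are unbiased.

    Returns an (N, 2) nm array; with ``return_labels=True`` also an (N,)
    integer array holding -1 for monomers and the dimer index for dimer
    members.
    """
    rng = np.random.default_rng(seed)
    side = math.sqrt(params.area) * 1000.0  # nm
    g = GUARD_BAND_NM
    full = side + 2.0 * g
    area_full_um2 = (full / 1000.0) ** 2

    n_mono = rng.poisson(params.density_monomers * area_full_um2)
    monomers = rng.uniform(-g, side + g, size=(n_mono, 2))

    n_dim = rng.poisson(params.density_dimers * area_full_um2)
    centres = rng.uniform(-g, side + g, size=(n_dim, 2))
    theta = rng.uniform(0.0, 2.0 * math.pi, size=n_dim)
    half = 0.5 * params.dimer_distance * np.column_stack([np.cos(theta), np.sin(theta)])
    dimer_pts = np.concatenate([centres - half, centres + half]) if n_dim else np.empty((0, 2))

    points = np.concatenate([monomers, dimer_pts])
    labels = np.concatenate(
        [np.full(n_mono, -1, dtype=int), np.tile(np.arange(n_dim), 2)]
    )
    if params.uncertainty > 0 and len(points):
        points = points + rng.normal(0.0, params.uncertainty, size=points.shape)

    keep = rng.random(len(points)) < params.labelling_efficiency
    points, labels = points[keep], labels[keep]
    core = np.all((points >= 0.0) & (points <= side), axis=1)
    points, labels = points[core], labels[core]
    if return_labels:
        return points, labels
    return points


def mixture_from_fit_params(
    dimer_distance: float,
    sigma_label: float,
    frac_of_dimers: float,
    observed_density: float,
    labelling_efficiency: float,
    area: float,
) -> MixtureParams:
    """Translate fit-space parameters into generative mixture parameters.

    ``frac_of_dimers`` is the percentage of molecules belonging to dimers
    (``frac_of_monomers = 100 - frac_of_dimers``). The total ground-truth
    molecule density is ``observed_density / labelling_efficiency``, so the
    observed (detectable) density matches the experimental value by
    construction; dimer pairs each carry two molecules.
    """
    if not 0.0 <= frac_of_dimers <= 100.0:
        raise ValidationError("frac_of_dimers must be in [0, 100]")
    if labelling_efficiency <= 0:
        raise ValidationError("labelling_efficiency must be > 0")
    rho_total = observed_density / labelling_efficiency  # molecules per um^2
    f = frac_of_dimers / 100.0
    return MixtureParams(
        density_monomers=(1.0 - f) * rho_total,
        density_dimers=f * rho_total / 2.0,
        dimer_distance=dimer_distance,
        uncertainty=sigma_label,
        labelling_efficiency=labelling_efficiency,
        area=area,
    )
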