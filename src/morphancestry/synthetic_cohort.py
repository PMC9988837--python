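"""Synthetic dense-landmark cohorts with known ground truth.

The study data this pipeline is designed for (dense facial quasi-landmarks
with regional European ancestry structure) are consent-restricted, so every
downstream stage is exercised on simulated cohorts that emulate the same
statistical structure:

* four regional subpopulations (North, South, East, West) with distinct,
  spatially smooth mean-shape deformations;
* linear covariate effects on shape (sex, age, height, weight, camera);
* genetic PC scores whose leading axes correlate with region (PC1 separates
  South from North/West, PC2 is an East-West gradient, PC3 a North-West
  contrast) plus non-regional noise PCs;
* Dirichlet admixture proportions concentrated on the true region;
* smooth low-rank individual variation plus landmark-level Gaussian noise
  (applied un-symmetrized, so faces carry mild bilateral asymmetry).

All ground-truth deformation fields are stored on the cohort so recovery can
be tested. Generation is fully deterministic given the seed: a single
``SeedSequence`` drives one stream for the shared fields and one substream
per individual, so subsetting a cohort never reshuffles another individual's
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AdmixtureQ, CohortShapes, CovariateTable, GeneticPCs

__all__ = [
    "Template",
    "GeneratorConfig",
    "SyntheticCohort",
    "make_template",
    "generate_cohort",
    "true_effect_map",
    "DEFAULT_REGIONS",
]

DEFAULT_REGIONS = ("North", "South", "East", "West")

#: Mean genetic PC score per region, rows PC1.. (columns follow
#: DEFAULT_REGIONS). PC1: South vs North/West; PC2: East vs West;
#: PC3: North vs West; PC4..: non-regional.
DEFAULT_PC_LOADINGS = np.array([
    [-1.5, 3.0, 0.0, -1.5],
    [0.0, 0.0, 3.0, -3.0],
    [1.5, 0.0, 0.0, -1.5],
])

#: Per-covariate field scale (RMS displacement in template units over the
#: covariate's coded range).
DEFAULT_COVARIATE_EFFECTS = {
    "sex": 0.5,
    "age": 0.02,
    "height": 0.02,
    "weight": 0.02,
    "camera": 0.3,
}


@dataclass
class Template:
    """Landmark topology: reference coordinates, triangulation and the
    bilateral (mirror) pairing of landmarks.

    The pairing is an involution: landmark ``i`` and ``symmetry_pairing[i]``
    are anatomical mirror images; midline landmarks map to themselves.
    """

    coordinates: np.ndarray
    triangulation: np.ndarray
    symmetry_pairing: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.triangulation = np.asarray(self.triangulation, dtype=int)
        self.symmetry_pairing = np.asarray(self.symmetry_pairing, dtype=int)
        L = len(self.coordinates)
        p = self.symmetry_pairing
        if not np.array_equal(p[p], np.arange(L)):
            raise ValueError("symmetry_pairing is not an involution")
        if self.triangulation.size and self.triangulation.max() >= L:
            raise ValueError("triangulation references a vertex index >= L")

    @property
    def n_landmarks(self) -> int:
        return len(self.coordinates)

    def mirror_error(self) -> float:
        """Max deviation between reflect(X)+pairing and the reference."""
        reflected = self.coordinates.copy()
        reflected[:, 0] *= -1
        return float(np.abs(reflected[self.symmetry_pairing] - self.coordinates).max())


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the study design: 186 individuals per region and 7160
    quasi-landmarks. Length units are "template units" (the default template
    spans ~100 units, a face-sized box if read as millimetres).
    """

    n_per_region: int = 186
    n_landmarks: int = 7160
    regions: tuple[str, ...] = DEFAULT_REGIONS
    region_effect_scale: float = 2.0
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    n_shape_modes: int = 10
    mode_sd: float = 1.0
    noise_sd: float = 0.5
    pc_region_loadings: np.ndarray = field(
        default_factory=lambda: DEFAULT_PC_LOADINGS.copy())
    n_pcs: int = 20
    dirichlet_concentration: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_landmarks < 9:
            raise ValueError("need at least 9 landmarks")
        if self.n_per_region < 2:
            raise ValueError("need at least 2 individuals per region")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")
        loadings = np.atleast_2d(np.asarray(self.pc_region_loadings, dtype=float))
        if loadings.shape[1] != len(self.regions):
            raise ValueError("pc_region_loadings columns must match regions")
        if self.n_pcs < max(4, loadings.shape[0]):
            raise ValueError("n_pcs must be >= 4 and cover all loading rows")
        full = np.zeros((self.n_pcs, len(self.regions)))
        full[: loadings.shape[0]] = loadings
        self.pc_region_loadings = full


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth that produced it."""

    shapes: CohortShapes
    covariates: CovariateTable
    pcs: GeneticPCs
    q: AdmixtureQ
    true_region: list[str]
    true_region_effect: np.ndarray      # (R, L, 3), zero mean over regions
    true_covariate_effects: dict[str, np.ndarray]  # name -> (L, 3)
    template: Template
    config: GeneratorConfig

    @property
    def region_names(self) -> tuple[str, ...]:
        return tuple(self.config.regions)

    def region_labels(self) -> np.ndarray:
        return np.asarray(self.true_region)

    def subset(self, mask_or_indices) -> "SyntheticCohort":
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SyntheticCohort(
            shapes=self.shapes.subset(idx),
            covariates=CovariateTable(self.covariates.table.iloc[idx].copy()),
            pcs=self.pcs.subset(idx),
            q=self.q.subset(idx),
            true_region=[self.true_region[i] for i in idx],
            true_region_effect=self.true_region_effect,
            true_covariate_effects=self.true_covariate_effects,
            template=self.template,
            config=self.config,
        )


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------

def _grid_factorization(L: int) -> tuple[int, int]:
    """Pick the most square nx*ny = L with nx, ny >= 3 (nx = columns)."""
    best = None
    for nx in range(3, int(np.sqrt(L)) + 1):
        if L % nx == 0 and L // nx >= 3:
            best = (nx, L // nx)
    if best is None:
        # nearest L admitting a factorization, for the error message
        for delta in range(1, L):
            for cand in (L - delta, L + delta):
                if cand >= 9 and _has_grid(cand):
                    raise ValueError(
                        f"L={L} admits no nx*ny grid with both factors >= 3; "
                        f"nearest valid L is {cand}")
        raise ValueError(f"L={L} admits no grid factorization")
    return best


def _has_grid(L: int) -> bool:
    return any(L % nx == 0 and L // nx >= 3 for nx in range(3, int(np.sqrt(L)) + 1))


def make_template(L: int = 7160, extent: float = 100.0) -> Template:
    """Build a face-like open surface: a smooth dome height field over an
    nx x ny grid, bilaterally symmetric about x = 0.

    The triangulation winds counter-clockwise viewed from +z, so +z is the
    outward normal direction. The symmetry pairing mirrors grid columns;
    when nx is odd the central column is self-paired (midline landmarks).
    """
    if L < 9:
        raise ValueError("need L >= 9")
    nx, ny = _grid_factorization(L)
    dx = extent / (nx - 1)
    x = (np.arange(nx) - (nx - 1) / 2) * dx
    y = (np.arange(ny) - (ny - 1) / 2) * dx
    xx, yy = np.meshgrid(x, y)          # shape (ny, nx), row-major
    sigma = extent / 2.0
    zz = 0.3 * extent * np.exp(-(xx ** 2 + yy ** 2) / (2 * sigma ** 2))
    coords = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    tris = []
    for iy in range(ny - 1):
        for ix in range(nx - 1):
            v00 = iy * nx + ix
            v10 = iy * nx + ix + 1
            v01 = (iy + 1) * nx + ix
            v11 = (iy + 1) * nx + ix + 1
            tris.append((v00, v10, v11))
            tris.append((v00, v11, v01))
    triangulation = np.asarray(tris, dtype=int)

    ix_grid = np.tile(np.arange(nx), ny)
    iy_grid = np.repeat(np.arange(ny), nx)
    pairing = iy_grid * nx + (nx - 1 - ix_grid)

    return Template(coords, triangulation, pairing)


# ---------------------------------------------------------------------------
# smooth random fields
# ---------------------------------------------------------------------------

def _symmetrize_field(field_: np.ndarray, template: Template) -> np.ndarray:
    """Bilateral symmetrization of a displacement field: average with the
    mirrored (X negated, landmarks re-paired) field."""
    mirrored = field_[template.symmetry_pairing].copy()
    mirrored[:, 0] *= -1
    return 0.5 * (field_ + mirrored)


def _project_shape_tangent(field_: np.ndarray, template: Template) -> np.ndarray:
    """Remove the translation, rotation and scaling components of a
    displacement field at the template, leaving a pure *shape* effect.

    Procrustes alignment quotients out similarity transforms, so ground
    truth effects must live in the orthogonal complement of that group's
    tangent space for downstream recovery to be well defined.
    """
    X0 = template.coordinates - template.coordinates.mean(axis=0)
    basis = []
    L = len(X0)
    for k in range(3):  # translations
        e = np.zeros((L, 3))
        e[:, k] = 1.0
        basis.append(e)
    gens = [np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0]], dtype=float),
            np.array([[0, 0, 1], [0, 0, 0], [-1, 0, 0]], dtype=float),
            np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float)]
    for g in gens:   # infinitesimal rotations
        basis.append(X0 @ g.T)
    basis.append(X0.copy())  # scaling
    B = np.stack([b.ravel() for b in basis], axis=1)
    q, _ = np.linalg.qr(B)
    f = field_.ravel()
    return (f - q @ (q.T @ f)).reshape(L, 3)


def _smooth_field(template: Template, rng: np.random.Generator,
                  n_bumps: int = 6, width_frac: float = 0.25,
                  symmetric: bool = True) -> np.ndarray:
    """A smooth random (L, 3) displacement field: a few Gaussian bumps with
    random centres and 3-vector amplitudes, bilaterally symmetrized,
    projected onto the shape tangent space and normalized to unit RMS."""
    coords = template.coordinates
    extent = float(np.ptp(coords[:, 0]))
    sigma = max(width_frac * extent, 1e-9)
    field_ = np.zeros_like(coords)
    centre_idx = rng.integers(0, len(coords), size=n_bumps)
    amps = rng.normal(size=(n_bumps, 3))
    for c, a in zip(centre_idx, amps):
        d2 = ((coords - coords[c]) ** 2).sum(axis=1)
        field_ += np.exp(-d2 / (2 * sigma ** 2))[:, None] * a
    if symmetric:
        field_ = _symmetrize_field(field_, template)
    field_ = _project_shape_tangent(field_, template)
    rms = np.sqrt((field_ ** 2).mean())
    if rms > 0:
        field_ /= rms
    return field_


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(cfg: GeneratorConfig, template: Template | None = None
                    ) -> SyntheticCohort:
    """Generate a cohort under ``cfg``.

    Each individual's configuration is
    ``template + region effect + sum(covariate effects) + individual modes
    + noise``. Region effect fields are centred across regions so the grand
    mean over a balanced cohort equals the template.
    """
    if template is None:
        template = make_template(cfg.n_landmarks)
    if template.n_landmarks != cfg.n_landmarks:
        raise ValueError("template landmark count does not match config")
    if cfg.n_shape_modes > 3 * cfg.n_landmarks:
        raise ValueError("n_shape_modes exceeds 3*L: covariance degenerate")

    R = len(cfg.regions)
    L = cfg.n_landmarks
    n = cfg.n_per_region * R

    ss = np.random.SeedSequence(cfg.seed)
    field_ss, indiv_ss = ss.spawn(2)
    field_rng = np.random.default_rng(field_ss)

    # shared ground-truth fields (drawn once, independent of n)
    region_fields = np.stack([
        _smooth_field(template, field_rng) * cfg.region_effect_scale
        for _ in range(R)])
    region_fields -= region_fields.mean(axis=0, keepdims=True)

    cov_fields = {
        name: _smooth_field(template, field_rng) * scale
        for name, scale in cfg.covariate_effects.items()
    }
    mode_fields = np.stack([
        _smooth_field(template, field_rng) * cfg.mode_sd
        for _ in range(cfg.n_shape_modes)]) if cfg.n_shape_modes else \
        np.zeros((0, L, 3))

    indiv_streams = indiv_ss.spawn(n)

    ids, regions, rows_cov = [], [], []
    coords = np.empty((n, L, 3))
    pc_scores = np.empty((n, cfg.n_pcs))
    q_rows = np.empty((n, R))

    cov_names = list(cfg.covariate_effects)
    for i in range(n):
        r = i // cfg.n_per_region
        region = cfg.regions[r]
        rng = np.random.default_rng(indiv_streams[i])

        cov = {
            "sex": float(rng.choice([-1.0, 1.0])),
            "age": float(rng.uniform(18, 65)),
            "height": float(rng.normal(170, 10)),
            "weight": float(rng.normal(75, 15)),
            "camera": float(rng.choice([-1.0, 1.0])),
        }

        shape = template.coordinates + region_fields[r]
        for name in cov_names:
            shape = shape + cov[name] * cov_fields[name]
        mode_scores = rng.normal(size=cfg.n_shape_modes)
        shape = shape + np.tensordot(mode_scores, mode_fields, axes=1)
        if cfg.noise_sd > 0:
            shape = shape + rng.normal(scale=cfg.noise_sd, size=(L, 3))

        pc_scores[i] = cfg.pc_region_loadings[:, r] + rng.normal(size=cfg.n_pcs)

        alpha = np.ones(R)
        alpha[r] = cfg.dirichlet_concentration
        q_rows[i] = rng.dirichlet(alpha)

        coords[i] = shape
        ids.append(f"{region[0]}{i:05d}")
        regions.append(region)
        rows_cov.append(cov)

    cov_df = pd.DataFrame(rows_cov, index=ids)
    cov_df.index.name = "id"
    cov_df["age_squared"] = cov_df["age"] ** 2

    return SyntheticCohort(
        shapes=CohortShapes(ids, coords),
        covariates=CovariateTable(cov_df),
        pcs=GeneticPCs(ids, pc_scores),
        q=AdmixtureQ(ids, q_rows, list(cfg.regions)),
        true_region=regions,
        true_region_effect=region_fields,
        true_covariate_effects=cov_fields,
        template=template,
        config=cfg,
    )


def true_effect_map(cohort: SyntheticCohort, region: str) -> np.ndarray:
    """The deformation field injected for ``region`` (ground truth)."""
    if region not in cohort.region_names:
        raise ValueError(f"unknown region {region!r}; cohort has "
                         f"{cohort.region_names}")
    return cohort.true_region_effect[cohort.region_names.index(region)]
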