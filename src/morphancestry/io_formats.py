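"""Readers and writers for every external format the pipeline touches.

Formats supported
-----------------
* wide coordinate CSV (``id, x1,y1,z1, ..., xL,yL,zL``; landmark indices are
  1-based in headers, 0-based everywhere in memory)
* directories of per-individual PLY/OBJ meshes in template correspondence
  (vertices taken in file order)
* PLINK ``.eigenvec`` dialect (optional header, with or without FID column)
* ADMIXTURE ``.Q`` dialect (one whitespace row of proportions per individual,
  no ids in the file)
* template JSON (coordinates + triangulation + bilateral pairing)
* per-vertex scalar maps as ASCII PLY (``quality`` property) plus CSV

All readers validate rather than silently reorder or renormalize; round trips
are lossless to well below 1e-9 relative error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortShapes",
    "CovariateTable",
    "GeneticPCs",
    "AdmixtureQ",
    "read_shapes",
    "write_shapes",
    "read_eigenvec",
    "write_eigenvec",
    "read_q",
    "write_q",
    "read_template_json",
    "write_template_json",
    "write_scalar_map",
    "read_scalar_map_csv",
    "write_mesh_ply",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CohortShapes:
    """A cohort of registered landmark configurations.

    ``coords`` has shape (n, L, 3); landmark ``j`` denotes the same anatomical
    point for every individual (template correspondence is assumed, as
    produced by dense non-rigid surface registration).
    """

    ids: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (n, L, 3), got {self.coords.shape}")
        if len(self.ids) != self.coords.shape[0]:
            raise ValueError("number of ids does not match number of configurations")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual ids")
        if not np.isfinite(self.coords).all():
            raise ValueError("coords contain non-finite values")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    def subset(self, mask_or_indices) -> "CohortShapes":
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CohortShapes([self.ids[i] for i in idx], self.coords[idx])


@dataclass
class CovariateTable:
    """Per-individual covariates entering the shape correction.

    Columns follow the study design: sex (coded -1/1), age in years,
    age_squared (derived from age when absent), height (cm), weight (kg),
    centroid_size (template units, filled in by the alignment stage) and
    camera system (coded -1/1).
    """

    table: pd.DataFrame

    REQUIRED = ("sex", "age", "height", "weight", "camera")

    def __post_init__(self) -> None:
        df = self.table
        if "id" in df.columns:
            df = df.set_index("id")
        df.index = df.index.astype(str)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"covariate table missing columns: {missing}")
        if "age_squared" not in df.columns:
            df = df.assign(age_squared=df["age"] ** 2)
        if (df["age"] < 18).any():
            raise ValueError("covariate table contains ages below 18")
        self.table = df

    @property
    def ids(self) -> list[str]:
        return list(self.table.index)

    def design_matrix(self, names: Sequence[str]) -> np.ndarray:
        missing = [c for c in names if c not in self.table.columns]
        if missing:
            raise ValueError(f"predictors not in covariate table: {missing}")
        return self.table.loc[:, list(names)].to_numpy(dtype=float)


@dataclass
class GeneticPCs:
    """Genetic ancestry principal-component scores, columns PC1..PCK."""

    ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be a 2-D (n, K) array")
        if len(self.ids) != self.scores.shape[0]:
            raise ValueError("ids and score rows differ in length")

    @property
    def n_pcs(self) -> int:
        return self.scores.shape[1]

    def subset(self, mask_or_indices) -> "GeneticPCs":
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GeneticPCs([self.ids[i] for i in idx], self.scores[idx])


@dataclass
class AdmixtureQ:
    """Supervised admixture proportions; rows sum to one."""

    ids: list[str]
    proportions: np.ndarray
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        q = np.asarray(self.proportions, dtype=float)
        if q.ndim != 2:
            raise ValueError("proportions must be 2-D (n, R)")
        if len(self.ids) != q.shape[0]:
            raise ValueError("ids and proportion rows differ in length")
        if (q < -1e-9).any() or (q > 1 + 1e-9).any():
            raise ValueError("admixture proportions must lie in [0, 1]")
        if q.shape[0]:
            sums = q.sum(axis=1)
            if np.abs(sums - 1.0).max() > 1e-6:
                raise ValueError("admixture rows must sum to 1 within 1e-6")
            q = q / sums[:, None]
        self.proportions = q
        if self.region_names and len(self.region_names) != q.shape[1]:
            raise ValueError("region_names length does not match Q columns")

    def subset(self, mask_or_indices) -> "AdmixtureQ":
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return AdmixtureQ([self.ids[i] for i in idx], self.proportions[idx],
                          list(self.region_names))


# ---------------------------------------------------------------------------
# wide CSV shapes
# ---------------------------------------------------------------------------

def _coord_columns(L: int) -> list[str]:
    cols = []
    for j in range(1, L + 1):
        cols += [f"x{j}", f"y{j}", f"z{j}"]
    return cols


def write_shapes(cohort: CohortShapes, path: str | Path) -> None:
    """Write a cohort as a wide CSV (one row per individual)."""
    L = cohort.n_landmarks
    flat = cohort.coords.reshape(cohort.n, 3 * L)
    df = pd.DataFrame(flat, columns=_coord_columns(L))
    df.insert(0, "id", cohort.ids)
    df.to_csv(path, index=False, float_format="%.17g")


def read_shapes(path: str | Path, template=None) -> CohortShapes:
    """Read a cohort from a wide CSV or a directory of PLY/OBJ meshes.

    When ``template`` is given, the landmark count of every individual is
    validated against it and mismatches are reported by id.
    """
    path = Path(path)
    if path.is_dir():
        return _read_mesh_dir(path, template)
    df = pd.read_csv(path)
    if df.columns[0] != "id":
        raise ValueError("wide shape CSV must start with an 'id' column")
    n_coord_cols = df.shape[1] - 1
    if n_coord_cols % 3 != 0:
        raise ValueError(
            f"expected 1 + 3*L columns, got {df.shape[1]} "
            f"({n_coord_cols} coordinate columns is not a multiple of 3)")
    L = n_coord_cols // 3
    if template is not None and L != len(template.coordinates):
        raise ValueError(
            f"CSV has L={L} landmarks but template has {len(template.coordinates)}")
    ids = df["id"].astype(str).tolist()
    coords = df.iloc[:, 1:].to_numpy(dtype=float).reshape(-1, L, 3)
    return CohortShapes(ids, coords)


def _read_mesh_dir(path: Path, template) -> CohortShapes:
    import trimesh

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".ply", ".obj"))
    if not files:
        raise ValueError(f"no PLY/OBJ meshes found in {path}")
    ids, coords = [], []
    L_expect = len(template.coordinates) if template is not None else None
    for f in files:
        mesh = trimesh.load(f, process=False, maintain_order=True)
        verts = np.asarray(mesh.vertices, dtype=float)
        if L_expect is None:
            L_expect = len(verts)
        if len(verts) != L_expect:
            raise ValueError(
                f"mesh {f.name}: {len(verts)} vertices, expected {L_expect} "
                "(template correspondence broken)")
        ids.append(f.stem)
        coords.append(verts)
    return CohortShapes(ids, np.stack(coords))


def write_mesh_ply(vertices: np.ndarray, faces: np.ndarray, path: str | Path,
                   scalars: np.ndarray | None = None) -> None:
    """Write an ASCII PLY mesh, optionally with a per-vertex ``quality``."""
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    lines = [
        "ply", "format ascii 1.0",
        f"element vertex {len(vertices)}",
        "property float x", "property float y", "property float z",
    ]
    if scalars is not None:
        scalars = np.asarray(scalars, dtype=float)
        lines.append("property float quality")
    lines += [f"element face {len(faces)}",
              "property list uchar int vertex_indices", "end_header"]
    for i, v in enumerate(vertices):
        row = f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}"
        if scalars is not None:
            row += f" {scalars[i]:.9g}"
        lines.append(row)
    for tri in faces:
        lines.append(f"3 {tri[0]} {tri[1]} {tri[2]}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PLINK .eigenvec
# ---------------------------------------------------------------------------

def read_eigenvec(path: str | Path) -> GeneticPCs:
    """Read genetic PC scores in the PLINK ``.eigenvec`` dialect.

    Whitespace delimited; an optional header line (``#FID IID PC1 ...`` or
    ``FID IID PC1 ...``); a leading FID column is optional and ignored —
    individual ids are taken from the IID column.
    """
    path = Path(path)
    raw = [ln.split() for ln in path.read_text().splitlines() if ln.strip()]
    if not raw:
        raise ValueError(f"{path} is empty")
    header = raw[0]
    has_header = header[0].lstrip("#").upper() in ("FID", "IID")
    if has_header:
        has_fid = header[0].lstrip("#").upper() == "FID"
        rows = raw[1:]
    else:
        rows = raw
        # no header: FID present when the first two fields are non-numeric
        has_fid = len(rows[0]) >= 2 and not _is_number(rows[0][1])
    width = len(rows[0])
    id_cols = 2 if has_fid else 1
    ids, scores = [], []
    for lineno, fields in enumerate(rows, start=2 if has_header else 1):
        if len(fields) != width:
            raise ValueError(f"{path}:{lineno}: ragged row "
                             f"({len(fields)} fields, expected {width})")
        ids.append(fields[id_cols - 1])
        try:
            scores.append([float(x) for x in fields[id_cols:]])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric PC score") from exc
    return GeneticPCs(ids, np.asarray(scores))


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_eigenvec(pcs: GeneticPCs, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#FID IID " + " ".join(f"PC{k+1}" for k in range(pcs.n_pcs)) + "\n")
        for i, iid in enumerate(pcs.ids):
            fh.write(f"0 {iid} " + " ".join(f"{v:.10g}" for v in pcs.scores[i]) + "\n")


# ---------------------------------------------------------------------------
# ADMIXTURE .Q
# ---------------------------------------------------------------------------

def read_q(path: str | Path, ids: Sequence[str],
           region_names: Sequence[str] | None = None) -> AdmixtureQ:
    """Read an ADMIXTURE ``.Q`` file; the file carries no ids, so the caller
    supplies them in file row order.

    Rows whose sum deviates from 1 by more than 1e-3 are rejected; smaller
    deviations are renormalized.
    """
    path = Path(path)
    rows = []
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        try:
            row = np.array([float(x) for x in ln.split()], dtype=float)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric proportion") from exc
        s = row.sum()
        if not (1 - 1e-3 <= s <= 1 + 1e-3):
            raise ValueError(
                f"{path}:{lineno}: admixture row sums to {s:.6g}, outside [0.999, 1.001]")
        rows.append(row / s)
    if len(rows) != len(ids):
        raise ValueError(f"{path}: {len(rows)} rows but {len(ids)} ids supplied")
    return AdmixtureQ(list(map(str, ids)), np.vstack(rows),
                      list(region_names) if region_names else [])


def write_q(q: AdmixtureQ, path: str | Path) -> None:
    np.savetxt(path, q.proportions, fmt="%.6f")


# ---------------------------------------------------------------------------
# template JSON
# ---------------------------------------------------------------------------

def write_template_json(template, path: str | Path) -> None:
    payload = {
        "coordinates": np.asarray(template.coordinates).tolist(),
        "triangulation": np.asarray(template.triangulation).tolist(),
        "symmetry_pairing": np.asarray(template.symmetry_pairing).tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_template_json(path: str | Path):
    from .synthetic_cohort import Template

    payload = json.loads(Path(path).read_text())
    return Template(
        coordinates=np.asarray(payload["coordinates"], dtype=float),
        triangulation=np.asarray(payload["triangulation"], dtype=int),
        symmetry_pairing=np.asarray(payload["symmetry_pairing"], dtype=int),
    )


# ---------------------------------------------------------------------------
# per-vertex scalar maps
# ---------------------------------------------------------------------------

def write_scalar_map(template, values: np.ndarray, path: str | Path,
                     allow_nan: bool = False) -> None:
    """Export one scalar per landmark as PLY (``quality``) and CSV.

    ``path`` is taken as the stem; ``<stem>.ply`` and ``<stem>.csv`` are
    written.
    """
    values = np.asarray(values, dtype=float)
    L = len(template.coordinates)
    if values.shape != (L,):
        raise ValueError(f"expected {L} scalar values, got shape {values.shape}")
    if np.isnan(values).any() and not allow_nan:
        raise ValueError("scalar map contains NaN (pass allow_nan=True to permit)")
    stem = Path(path)
    if stem.suffix in (".ply", ".csv"):
        stem = stem.with_suffix("")
    write_mesh_ply(template.coordinates, template.triangulation,
                   stem.with_suffix(".ply"), scalars=values)
    pd.DataFrame({
        "landmark_index": np.arange(1, L + 1),
        "value": values,
    }).to_csv(stem.with_suffix(".csv"), index=False, float_format="%.17g")


def read_scalar_map_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    return df["value"].to_numpy(dtype=float)
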