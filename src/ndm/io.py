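"""Tabular readers and writers.

One dialect everywhere: RFC-4180 CSV, UTF-8, ``.`` decimal.  Landscapes are
long tables with one row per surveyed cell (`cell_id,row,col,habitat,viable`
plus one column per covariate); cells of the bounding grid absent from the
table are non-viable padding.  Richness caps travel in a small YAML/dict
config (``caps: {habitat: int|null}``).  Species live in two files: a
species table (id, dispersal parameters, persistence-model declaration) and
an optional long coefficient table for logistic models mirroring the usual
GLM output (`species_id,term,estimate` with an ``(Intercept)`` row).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .estimation import ObservationSet
from .landscape import Landscape
from .persistence import (
    ConstantPersistence,
    LogisticPersistence,
    SpeciesSpec,
    ThresholdPersistence,
)
from .simulator import OccupancyField, OccupancyState

__all__ = [
    "read_landscape_csv",
    "write_landscape_csv",
    "read_species_csv",
    "write_species_csv",
    "read_state_csv",
    "write_state_csv",
    "write_field_csv",
    "read_field_csv",
    "write_ascii_grid",
    "write_provenance",
    "load_caps",
]

_LANDSCAPE_COLS = ["cell_id", "row", "col", "habitat", "viable"]


def load_caps(source: str | Path | Mapping) -> dict[str, int | None]:
    """Richness caps from a mapping or a YAML file with a ``caps:`` block."""
    if isinstance(source, Mapping):
        caps = dict(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
        caps = doc.get("caps", doc) if isinstance(doc, dict) else {}
    return {str(k): (None if v is None else int(v)) for k, v in caps.items()}


def read_landscape_csv(
    path: str | Path,
    caps: str | Path | Mapping,
    cell_side_km: float = 1.0,
) -> Landscape:
    """Validated landscape from a per-cell CSV plus a richness-cap config."""
    df = pd.read_csv(path)
    missing = [c for c in _LANDSCAPE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    dup = df["cell_id"][df["cell_id"].duplicated()]
    if not dup.empty:
        rows = [int(i) + 2 for i in dup.index[:5]]  # +2: header + 0-base
        raise ValueError(f"{path}: duplicate cell_id at line(s) {rows}")
    for col in ("row", "col"):
        vals = df[col]
        if not np.array_equal(vals, vals.astype(int)) or (vals < 0).any():
            bad = int(vals.index[(vals != vals.astype(int)) | (vals < 0)][0]) + 2
            raise ValueError(f"{path}: non-integer or negative {col} at line {bad}")
    n_rows = int(df["row"].max()) + 1
    n_cols = int(df["col"].max()) + 1
    shape = (n_rows, n_cols)
    habitat = np.full(shape, "outside", dtype=object)
    viable = np.zeros(shape, dtype=bool)
    cell_ids = np.full(shape, None, dtype=object)
    cov_names = [c for c in df.columns if c not in _LANDSCAPE_COLS]
    covariates = {name: np.full(shape, np.nan) for name in cov_names}
    r, c = df["row"].to_numpy(int), df["col"].to_numpy(int)
    habitat[r, c] = df["habitat"].astype(str).to_numpy()
    viable[r, c] = df["viable"].astype(bool).to_numpy()
    cell_ids[r, c] = df["cell_id"].to_numpy()
    for name in cov_names:
        covariates[name][r, c] = df[name].to_numpy(float)
    cap_map = load_caps(caps)
    cap_map.setdefault("outside", None)
    return Landscape(
        n_rows=n_rows,
        n_cols=n_cols,
        habitat=habitat,
        viable=viable,
        covariates=covariates,
        richness_cap=cap_map,
        cell_side_km=cell_side_km,
        cell_ids=cell_ids,
    )


def _cell_id(L: Landscape, r: int, c: int) -> str:
    if L.cell_ids is not None and L.cell_ids[r, c] is not None:
        return str(L.cell_ids[r, c])
    return f"r{r}c{c}"


def write_landscape_csv(L: Landscape, path: str | Path, viable_only: bool = False) -> Path:
    rows = []
    for r in range(L.n_rows):
        for c in range(L.n_cols):
            if viable_only and not L.viable[r, c]:
                continue
            row = {
                "cell_id": _cell_id(L, r, c),
                "row": r,
                "col": c,
                "habitat": str(L.habitat[r, c]),
                "viable": bool(L.viable[r, c]),
            }
            for name, arr in L.covariates.items():
                row[name] = arr[r, c]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


# -- species ---------------------------------------------------------------


def read_species_csv(
    path: str | Path,
    coeff_path: str | Path | None = None,
    covariate_schema: Sequence[str] | None = None,
) -> list[SpeciesSpec]:
    """Species specs from a species table plus an optional coefficient table.

    The species table needs ``species_id,p_max,model`` and, per species,
    exactly one of ``d_max``/``d_min``.  ``model`` is ``constant`` (column
    ``p``), ``threshold`` (columns ``covariate,cutoff,p_below,p_at_or_above``)
    or ``logistic`` (coefficient rows in ``coeff_path``).
    """
    df = pd.read_csv(path)
    for col in ("species_id", "p_max", "model"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    coeffs: dict[str, dict[str, float]] = {}
    if coeff_path is not None:
        cdf = pd.read_csv(coeff_path)
        for col in ("species_id", "term", "estimate"):
            if col not in cdf.columns:
                raise ValueError(f"{coeff_path}: missing required column {col!r}")
        for sid, grp in cdf.groupby("species_id"):
            coeffs[str(sid)] = dict(zip(grp["term"].astype(str), grp["estimate"].astype(float)))
        orphans = set(coeffs) - set(df["species_id"].astype(str))
        if orphans:
            raise ValueError(f"{coeff_path}: coefficients for unknown species {sorted(orphans)}")
    specs = []
    for _, row in df.iterrows():
        sid = str(row["species_id"])
        model = str(row["model"])
        if model == "constant":
            pers = ConstantPersistence(float(row["p"]))
        elif model == "threshold":
            pers = ThresholdPersistence(
                covariate=str(row["covariate"]),
                cutoff=float(row["cutoff"]),
                p_below=float(row["p_below"]),
                p_at_or_above=float(row["p_at_or_above"]),
            )
        elif model == "logistic":
            if sid not in coeffs:
                raise ValueError(f"{path}: logistic species {sid!r} has no coefficient rows")
            terms = dict(coeffs[sid])
            if "(Intercept)" not in terms:
                raise ValueError(f"{coeff_path}: species {sid!r} missing '(Intercept)' term")
            intercept = terms.pop("(Intercept)")
            pers = LogisticPersistence(intercept, terms)
        else:
            raise ValueError(f"{path}: unknown persistence model {model!r} for {sid!r}")
        if covariate_schema is not None:
            unknown = pers.required_covariates() - set(covariate_schema)
            if unknown:
                raise ValueError(f"species {sid!r} references unknown covariate(s) {sorted(unknown)}")

        def _opt(col: str) -> int | None:
            if col in row and pd.notna(row[col]):
                return int(row[col])
            return None

        specs.append(
            SpeciesSpec(
                species_id=sid,
                p_max=float(row["p_max"]),
                d_max=_opt("d_max"),
                d_min=_opt("d_min"),
                persistence=pers,
            )
        )
    return specs


def write_species_csv(
    species: Sequence[SpeciesSpec], path: str | Path, coeff_path: str | Path | None = None
) -> Path:
    rows, crow = [], []
    for s in species:
        row = {
            "species_id": s.species_id,
            "p_max": s.p_max,
            "d_max": s.d_max,
            "d_min": s.d_min,
            "model": s.persistence.variant,
        }
        if isinstance(s.persistence, ConstantPersistence):
            row["p"] = s.persistence.p
        elif isinstance(s.persistence, ThresholdPersistence):
            row.update(
                covariate=s.persistence.covariate,
                cutoff=s.persistence.cutoff,
                p_below=s.persistence.p_below,
                p_at_or_above=s.persistence.p_at_or_above,
            )
        elif isinstance(s.persistence, LogisticPersistence):
            crow.append({"species_id": s.species_id, "term": "(Intercept)",
                         "estimate": s.persistence.intercept})
            for term, est in s.persistence.coefficients.items():
                crow.append({"species_id": s.species_id, "term": term, "estimate": est})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    if crow:
        if coeff_path is None:
            raise ValueError("logistic species present but no coeff_path given")
        pd.DataFrame(crow).to_csv(coeff_path, index=False)
    return Path(path)


# -- states and fields -----------------------------------------------------


def _id_grid(L: Landscape) -> dict[str, tuple[int, int]]:
    return {
        _cell_id(L, r, c): (r, c) for r in range(L.n_rows) for c in range(L.n_cols)
    }


def write_state_csv(
    state: OccupancyState, species_ids: Sequence[str], L: Landscape, path: str | Path
) -> Path:
    rows = []
    for i, sid in enumerate(species_ids):
        for r, c in zip(*np.nonzero(state.presence[i])):
            rows.append({"species_id": sid, "cell_id": _cell_id(L, r, c), "present": 1})
    pd.DataFrame(rows, columns=["species_id", "cell_id", "present"]).to_csv(path, index=False)
    return Path(path)


def read_state_csv(
    path: str | Path, species_ids: Sequence[str], L: Landscape
) -> OccupancyState:
    df = pd.read_csv(path)
    for col in ("species_id", "cell_id", "present"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    idx = {sid: i for i, sid in enumerate(species_ids)}
    cells = _id_grid(L)
    presence = np.zeros((len(species_ids), L.n_rows, L.n_cols), dtype=bool)
    for _, row in df.iterrows():
        sid, cid = str(row["species_id"]), str(row["cell_id"])
        if sid not in idx:
            raise ValueError(f"{path}: unknown species_id {sid!r}")
        if cid not in cells:
            raise ValueError(f"{path}: unknown cell_id {cid!r}")
        if bool(row["present"]):
            presence[idx[sid]][cells[cid]] = True
    return OccupancyState(presence, 0)


def write_field_csv(field: OccupancyField, L: Landscape, path: str | Path) -> Path:
    rows = []
    for i, sid in enumerate(field.species_ids):
        for r in range(L.n_rows):
            for c in range(L.n_cols):
                if L.viable[r, c]:
                    rows.append(
                        {"species_id": sid, "cell_id": _cell_id(L, r, c),
                         "probability": field.probability[i, r, c]}
                    )
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def read_field_csv(path: str | Path, L: Landscape) -> OccupancyField:
    df = pd.read_csv(path)
    species_ids = list(dict.fromkeys(df["species_id"].astype(str)))
    idx = {sid: i for i, sid in enumerate(species_ids)}
    cells = _id_grid(L)
    probs = np.zeros((len(species_ids), L.n_rows, L.n_cols))
    for _, row in df.iterrows():
        probs[idx[str(row["species_id"])]][cells[str(row["cell_id"])]] = float(
            row["probability"]
        )
    return OccupancyField(probs, species_ids, replicates=0, seed=0)


def observations_from_state(state: OccupancyState, species_ids: Sequence[str]) -> ObservationSet:
    return ObservationSet(state.presence.copy(), list(species_ids))


def write_ascii_grid(
    values: np.ndarray,
    path: str | Path,
    cellsize: float = 1.0,
    nodata: float = -9999.0,
    mask: np.ndarray | None = None,
) -> Path:
    """Per-cell scalar map as an ESRI ASCII grid (masked cells -> NODATA)."""
    values = np.asarray(values, dtype=float)
    out = values.copy()
    if mask is not None:
        out = np.where(np.asarray(mask, dtype=bool), out, nodata)
    n_rows, n_cols = out.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {n_cols}\nnrows {n_rows}\n")
        fh.write("xllcorner 0.0\nyllcorner 0.0\n")
        fh.write(f"cellsize {cellsize}\nNODATA_value {nodata}\n")
        for r in range(n_rows):
            fh.write(" ".join(f"{v:g}" for v in out[r]) + "\n")
    return Path(path)


def write_provenance(path: str | Path, command: str, params: Mapping) -> Path:
    """Record what produced a run's outputs (command, parameters, versions)."""
    import ndm

    doc = {
        "command": command,
        "params": {k: v for k, v in params.items()},
        "versions": {"ndm": ndm.__version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    path = Path(path)
    path.write_text(json.dumps(doc, indent=2, default=str) + "\n")
    return path
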