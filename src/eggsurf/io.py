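"""Readers and writers for the pipeline's on-disk formats.

Height maps travel in a plain-text grid dialect (human-diffable, bitwise
round-trippable) or single-channel TIFF; phylogenies are Newick; trait and
result tables are delimited text.  Heights are stored in nanometres and pixel
pitch in micrometres throughout — unit conversions happen only at this
boundary, never inside the analysis modules.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("eggsurf")

__all__ = [
    "HeightMap",
    "TraitRecord",
    "RunConfig",
    "HeightMapFormatError",
    "TreeFormatError",
    "TraitTableError",
    "read_height_map",
    "write_height_map",
    "read_tree",
    "write_tree",
    "read_trait_table",
    "write_trait_table",
    "trait_records_to_frame",
    "frame_to_trait_records",
    "write_table",
    "CATEGORICAL_LEVELS",
    "CONTINUOUS_PREDICTORS",
    "ALL_PREDICTORS",
]


class HeightMapFormatError(ValueError):
    """Raised when a height-map file cannot be parsed."""


class TreeFormatError(ValueError):
    """Raised when a Newick tree violates the pipeline's requirements."""


class TraitTableError(ValueError):
    """Raised when a trait table has unknown columns, levels or ids."""


# ---------------------------------------------------------------------------
# HeightMap
# ---------------------------------------------------------------------------

@dataclass
class HeightMap:
    """A rectangular grid of surface heights with a per-pixel validity mask.

    Parameters
    ----------
    heights
        (nrow, ncol) float array of heights in nm.  Invalid pixels hold NaN
        and must never be read as heights.
    valid
        (nrow, ncol) boolean mask; True where the profilometer returned data.
    pitch_x, pitch_y
        Pixel pitch in µm along columns (x) and rows (y).
    meta
        Free-form metadata (specimen id, scan index, pigment region tag
        ``whole``/``foreground``/``background``, ``corrected`` flag, ...).
    """

    heights: np.ndarray
    valid: np.ndarray
    pitch_x: float
    pitch_y: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.heights.ndim != 2 or self.heights.shape[0] < 2 or self.heights.shape[1] < 2:
            raise ValueError("height grid must be 2-D with nrow >= 2 and ncol >= 2")
        if self.valid.shape != self.heights.shape:
            raise ValueError("validity mask shape must match height grid")
        if not (self.pitch_x > 0 and self.pitch_y > 0):
            raise ValueError("pixel pitch must be positive")
        if not np.all(np.isfinite(self.heights[self.valid])):
            raise ValueError("heights at valid pixels must be finite")
        # enforce the sentinel at invalid pixels
        self.heights = self.heights.copy()
        self.heights[~self.valid] = np.nan

    @property
    def nrow(self) -> int:
        return self.heights.shape[0]

    @property
    def ncol(self) -> int:
        return self.heights.shape[1]

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def coverage(self) -> float:
        return self.n_valid / self.heights.size

    def valid_heights(self) -> np.ndarray:
        """The multiset of heights at valid pixels, as a 1-D array."""
        return self.heights[self.valid]


_HEADER_KEYS = ("nrow", "ncol", "pitch_x_um", "pitch_y_um")


def read_height_map(path, dialect: str = "grid-text", *,
                    pitch_x: float = 1.0, pitch_y: float = 1.0) -> HeightMap:
    """Read a height map.

    ``grid-text`` is the native dialect (see :func:`write_height_map`);
    ``tiff`` reads a single-channel float TIFF where NaN marks invalid
    pixels (pitch must then be supplied, TIFF carries none).
    """
    path = Path(path)
    if dialect == "tiff":
        import tifffile

        arr = np.asarray(tifffile.imread(path), dtype=float)
        if arr.ndim != 2:
            raise HeightMapFormatError(f"{path}: expected a single-channel image")
        return HeightMap(arr, np.isfinite(arr), pitch_x, pitch_y)
    if dialect != "grid-text":
        raise ValueError(f"unknown height-map dialect {dialect!r}")

    meta: dict = {}
    header: dict = {}
    rows: list[list[float]] = []
    mask_rows: list[list[bool]] = []
    with open(path) as fh:
        lineno = 0
        header_idx = 0
        for raw in fh:
            lineno += 1
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            if header_idx < len(_HEADER_KEYS):
                parts = line.split()
                key = _HEADER_KEYS[header_idx]
                if len(parts) != 2 or parts[0] != key:
                    raise HeightMapFormatError(
                        f"{path}:{lineno}: expected header line '{key} <value>', got {line!r}")
                try:
                    header[key] = float(parts[1])
                except ValueError:
                    raise HeightMapFormatError(
                        f"{path}:{lineno}: non-numeric value in header line {line!r}") from None
                header_idx += 1
                continue
            tokens = line.split()
            vals, ok = [], []
            for tok in tokens:
                if tok.lower() == "nan":
                    vals.append(np.nan)
                    ok.append(False)
                else:
                    try:
                        vals.append(float(tok))
                    except ValueError:
                        raise HeightMapFormatError(
                            f"{path}:{lineno}: bad height token {tok!r}") from None
                    ok.append(True)
            rows.append(vals)
            mask_rows.append(ok)
    if header_idx < len(_HEADER_KEYS):
        raise HeightMapFormatError(f"{path}: truncated header, missing "
                                   f"{_HEADER_KEYS[header_idx]!r}")
    nrow, ncol = int(header["nrow"]), int(header["ncol"])
    if len(rows) != nrow:
        raise HeightMapFormatError(f"{path}: expected {nrow} data rows, found {len(rows)}")
    widths = {len(r) for r in rows}
    if widths != {ncol}:
        raise HeightMapFormatError(
            f"{path}: non-rectangular data, row widths {sorted(widths)} (expected {ncol})")
    heights = np.array(rows, dtype=float)
    valid = np.array(mask_rows, dtype=bool)
    return HeightMap(heights, valid, header["pitch_x_um"], header["pitch_y_um"], meta)


def write_height_map(hm: HeightMap, path) -> None:
    """Write the grid-text dialect.  Floats use %.17g so that a read-back
    reproduces the array bitwise."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# eggsurf height map v1\n")
        for k, v in hm.meta.items():
            fh.write(f"# {k}: {v}\n")
        fh.write(f"nrow {hm.nrow}\n")
        fh.write(f"ncol {hm.ncol}\n")
        fh.write(f"pitch_x_um {hm.pitch_x:.17g}\n")
        fh.write(f"pitch_y_um {hm.pitch_y:.17g}\n")
        for i in range(hm.nrow):
            toks = [
                f"{hm.heights[i, j]:.17g}" if hm.valid[i, j] else "NaN"
                for j in range(hm.ncol)
            ]
            fh.write(" ".join(toks) + "\n")


# ---------------------------------------------------------------------------
# Phylogenies
# ---------------------------------------------------------------------------

def read_tree(path) -> dendropy.Tree:
    """Read a rooted Newick tree, requiring branch lengths on every non-root
    edge and unique tip labels."""
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon is not None]
    n_leaves = sum(1 for _ in tree.leaf_node_iter())
    if len(labels) != n_leaves:
        raise TreeFormatError("tree contains unlabelled tips")
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise TreeFormatError(f"duplicate tip label {lab!r}")
        seen.add(lab)
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        if nd.edge.length is None:
            who = nd.taxon.label if nd.taxon else "an internal node"
            raise TreeFormatError(f"missing branch length on the edge above {who}")
        if nd.edge.length < 0:
            who = nd.taxon.label if nd.taxon else "an internal node"
            raise TreeFormatError(f"negative branch length above {who}")
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------

#: Allowed levels of the ten categorical life-history predictors.
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "maculation": ("immaculate", "maculate"),
    "diet": ("plant", "insectivore", "omnivore", "carnivore/scavenger"),
    "development": ("altricial", "precocial"),
    "nest_type": ("exposed", "semi-enclosed", "enclosed"),
    "nest_location": ("ground", "water", "elevated"),
    "habitat": ("open", "semi-open", "dense"),
    "nest_lining": ("lined", "not lined"),
    "incubating_parent": ("not shared", "shared"),
    "parental_contact": ("wet plumage", "dry plumage"),
    "parental_care": ("uniparental", "biparental"),
}

#: The five continuous predictors (units in the column names).
CONTINUOUS_PREDICTORS: tuple[str, ...] = (
    "body_mass_g",
    "clutch_size",
    "incubation_period_d",
    "annual_mean_temp",
    "annual_mean_precip",
)

ALL_PREDICTORS: tuple[str, ...] = CONTINUOUS_PREDICTORS + tuple(CATEGORICAL_LEVELS)


@dataclass
class TraitRecord:
    """One species' life-history predictors (15 total: 5 continuous, 10
    categorical).  Missing values are None (continuous) / None (categorical),
    never silently imputed."""

    species: str
    body_mass_g: Optional[float] = None
    clutch_size: Optional[float] = None
    incubation_period_d: Optional[float] = None
    annual_mean_temp: Optional[float] = None
    annual_mean_precip: Optional[float] = None
    maculation: Optional[str] = None
    diet: Optional[str] = None
    development: Optional[str] = None
    nest_type: Optional[str] = None
    nest_location: Optional[str] = None
    habitat: Optional[str] = None
    nest_lining: Optional[str] = None
    incubating_parent: Optional[str] = None
    parental_contact: Optional[str] = None
    parental_care: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.species:
            raise TraitTableError("species id absent")
        for name, levels in CATEGORICAL_LEVELS.items():
            val = getattr(self, name)
            if val is not None and val not in levels:
                raise TraitTableError(
                    f"unknown level {val!r} for {name!r} "
                    f"(species {self.species!r}); allowed: {levels}")
        for name in CONTINUOUS_PREDICTORS:
            val = getattr(self, name)
            if val is not None and not np.isfinite(val):
                raise TraitTableError(
                    f"non-finite value for {name!r} (species {self.species!r})")


def read_trait_table(path, sep: str = ",") -> list[TraitRecord]:
    """Read a delimited trait table into validated :class:`TraitRecord` rows."""
    df = pd.read_csv(path, sep=sep, comment="#", dtype={"species": str})
    if "species" not in df.columns:
        raise TraitTableError(f"{path}: no 'species' column")
    return frame_to_trait_records(df, context=str(path))


def frame_to_trait_records(df: pd.DataFrame, context: str = "<frame>") -> list[TraitRecord]:
    records = []
    for idx, row in df.iterrows():
        kwargs: dict = {"species": row["species"]}
        if pd.isna(row["species"]):
            raise TraitTableError(f"{context}: row {idx}: species id absent")
        for name in CONTINUOUS_PREDICTORS:
            if name in df.columns and not pd.isna(row[name]):
                kwargs[name] = float(row[name])
        for name in CATEGORICAL_LEVELS:
            if name in df.columns and not pd.isna(row[name]):
                kwargs[name] = str(row[name])
        try:
            records.append(TraitRecord(**kwargs))
        except TraitTableError as err:
            raise TraitTableError(f"{context}: row {idx}: {err}") from None
    return records


def trait_records_to_frame(records: Sequence[TraitRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def write_trait_table(records: Sequence[TraitRecord], path, sep: str = ",") -> None:
    trait_records_to_frame(records).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Run configuration and generic result tables
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline-wide settings.  Defaults mirror the study's stated thresholds
    (40% coverage, second-order form correction) and its posterior-prediction
    MCMC controls (80 000 iterations, 20 000 burn-in, thinning 500)."""

    seed: int = 0
    coverage_threshold: float = 0.40
    min_area_px: int = 10000
    poly_order: int = 2
    cooks_cutoff: Optional[float] = None  # None -> 4/n
    log10_transform_sa: bool = True
    log10_transform_sku: bool = True
    mcmc_iterations: int = 80000
    mcmc_burn_in: int = 20000
    mcmc_thinning: int = 500
    prior_variance_shape: float = 0.001
    prior_variance_scale: float = 0.001
    fixed_effect_prior_variance: float = 1e8
    grid_bins: int = 3
    batch_size: int = 500
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.coverage_threshold <= 1):
            raise ValueError("coverage threshold must lie in (0, 1]")
        if not (self.mcmc_iterations > self.mcmc_burn_in >= 0):
            raise ValueError("need iterations > burn-in >= 0")
        if self.mcmc_thinning < 1:
            raise ValueError("thinning must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        """Short stable hash of the configuration, recorded in outputs."""
        payload = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, *, seed: Optional[int] = None,
                config: Optional[RunConfig] = None, sep: str = ",") -> None:
    """Write a result table with a header comment recording seed and config
    hash, so every output is traceable to the run that made it."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        if config is not None:
            fh.write(f"# config_sha1: {config.digest()}\n")
        df.to_csv(fh, sep=sep, index=False)


def read_table(path, sep: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")
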