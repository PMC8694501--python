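"""Shared data model and I/O.

Every stage of the pipeline exchanges the same small set of containers:
:class:`OmicsLayer` (one feature x sample matrix with a declared kind),
:class:`MultiOmicsDataset` (sample-aligned layers plus a clinical table) and
:class:`GeneSetCollection` (GMT gene sets).  Matrices are stored
features-in-rows / samples-in-columns, the transcriptomics convention.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("moclust")

LAYER_KINDS = ("gaussian", "beta", "binary")

#: clinical table columns expected by the survival stage
CLINICAL_COLUMNS = ("rfs_months", "rfs_event", "age", "psa", "t_stage", "gleason")


@dataclass
class OmicsLayer:
    """One omics data layer.

    Parameters
    ----------
    name : str
        Layer label, e.g. ``"mRNA"`` or ``"methylation"``.
    kind : {"gaussian", "beta", "binary"}
        Value domain: unbounded continuous, [0, 1] beta values, or 0/1
        indicators (somatic mutation calls).
    values : pandas.DataFrame
        Feature x sample numeric matrix. Index = feature IDs,
        columns = sample IDs, both unique.
    """

    name: str
    kind: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}; expected one of {LAYER_KINDS}")
        if self.values.index.has_duplicates:
            raise ValueError(f"layer {self.name!r}: duplicate feature IDs")
        if self.values.columns.has_duplicates:
            raise ValueError(f"layer {self.name!r}: duplicate sample IDs")
        vals = self.values.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError(f"layer {self.name!r}: non-numeric values")
        if np.isnan(vals).any():
            raise ValueError(f"layer {self.name!r}: missing values present after load")
        if self.kind == "beta" and (vals.min() < 0 or vals.max() > 1):
            raise ValueError(f"layer {self.name!r}: beta values outside [0, 1]")
        if self.kind == "binary" and not np.isin(vals, (0, 1)).all():
            raise ValueError(f"layer {self.name!r}: binary layer contains values outside {{0, 1}}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def zscored(self) -> np.ndarray:
        """Per-feature z-scores (features x samples); constant rows map to 0."""
        vals = self.values.to_numpy(dtype=float)
        mu = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (vals - mu) / sd


@dataclass
class MultiOmicsDataset:
    """Ordered collection of sample-aligned omics layers plus a clinical table.

    All layers share an identical, identically ordered sample ID vector;
    the clinical table (if present) is indexed by the same sample IDs.
    """

    layers: list[OmicsLayer]
    clinical: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("dataset needs at least one layer")
        ref = self.layers[0].sample_ids
        for layer in self.layers[1:]:
            if layer.sample_ids != ref:
                raise ValueError(
                    f"layer {layer.name!r} sample IDs differ from layer {self.layers[0].name!r}"
                )
        if self.clinical is not None:
            if list(self.clinical.index) != ref:
                raise ValueError("clinical table index does not match layer sample IDs")
            validate_clinical(self.clinical)

    @property
    def sample_ids(self) -> list[str]:
        return self.layers[0].sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def layer(self, name: str) -> OmicsLayer:
        for lyr in self.layers:
            if lyr.name == name:
                return lyr
        raise KeyError(f"no layer named {name!r}")

    def continuous_layers(self) -> list[OmicsLayer]:
        return [l for l in self.layers if l.kind in ("gaussian", "beta")]

    def concat_continuous(self, zscore: bool = True) -> np.ndarray:
        """Samples x features matrix concatenating all continuous layers."""
        cont = self.continuous_layers()
        if not cont:
            raise ValueError("dataset has no continuous layer")
        blocks = [l.zscored() if zscore else l.values.to_numpy(dtype=float) for l in cont]
        return np.vstack(blocks).T


def validate_clinical(clinical: pd.DataFrame) -> None:
    """Sanity-check a clinical table (survival columns, if present)."""
    if "rfs_months" in clinical:
        t = clinical["rfs_months"].to_numpy(dtype=float)
        if np.nanmin(t) < 0:
            raise ValueError("clinical table: negative survival times")
    if "rfs_event" in clinical:
        ev = clinical["rfs_event"].dropna().to_numpy(dtype=float)
        if not np.isin(ev, (0, 1)).all():
            raise ValueError("clinical table: rfs_event must be 0/1")


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT content): ``sets[name] -> ordered unique gene IDs``."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


# ---------------------------------------------------------------------------
# matrix / label / GMT readers and writers


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first or "," not in first else ","


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample TSV/CSV matrix (delimiter auto-detected)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        bad = _first_non_numeric(df)
        raise ValueError(f"non-numeric cell in {path.name} at row={bad[0]!r}, column={bad[1]!r}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def _first_non_numeric(df: pd.DataFrame) -> tuple[str, str]:
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            return str(df.index[bad.argmax()]), str(col)
    return "?", "?"


def write_matrix(matrix: pd.DataFrame | np.ndarray, path: str | Path) -> None:
    """Write a matrix as TSV; round-trips with :func:`read_matrix` within 1e-12."""
    if isinstance(matrix, np.ndarray):
        matrix = pd.DataFrame(
            matrix,
            index=[f"r{i}" for i in range(matrix.shape[0])],
            columns=[f"c{j}" for j in range(matrix.shape[1])],
        )
    matrix.to_csv(path, sep="\t", float_format="%.17g")


def write_labels(labels: Sequence[int], path: str | Path, sample_ids: Sequence[str] | None = None) -> None:
    labels = list(labels)
    if not labels:
        raise ValueError("empty label vector: nothing to write")
    if sample_ids is None:
        sample_ids = [f"S{i + 1:04d}" for i in range(len(labels))]
    pd.DataFrame({"sample_id": list(sample_ids), "label": labels}).to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["label"].to_numpy(), index=df["sample_id"].astype(str), name="label")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...`` per line.

    Genes are de-duplicated preserving first occurrence; duplicate set names
    and lines with fewer than three fields are errors.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT parse error at line {lineno}: fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"GMT parse error at line {lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection | Mapping[str, Sequence[str]], path: str | Path) -> None:
    items = collection.sets.items() if isinstance(collection, GeneSetCollection) else collection.items()
    with open(path, "w") as fh:
        for name, genes in items:
            fh.write("\t".join([name, "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# bundle loading


def _load_mutation_pairs(path: Path) -> pd.DataFrame:
    """Densify a two-column gene<TAB>sample mutation pair list into a 0/1 matrix."""
    pairs = pd.read_csv(path, sep=_detect_sep(path), header=None, names=["gene", "sample"])
    mat = pd.crosstab(pairs["gene"].astype(str), pairs["sample"].astype(str))
    return (mat > 0).astype(float)


def _looks_like_pairs(path: Path) -> bool:
    head = pd.read_csv(path, sep=_detect_sep(path), header=None, nrows=5)
    if head.shape[1] != 2:
        return False
    return all(head[c].dtype == object for c in head.columns)


def load_omics_bundle(
    layer_files: Iterable[tuple[str | Path, str, str]],
    clinical_path: str | Path | None = None,
    max_missing_frac: float = 0.2,
) -> MultiOmicsDataset:
    """Load layer files into a sample-aligned :class:`MultiOmicsDataset`.

    Parameters
    ----------
    layer_files :
        Iterable of ``(path, kind, name)`` triples. Binary layers may be
        given either as dense 0/1 matrices or as two-column gene/sample
        mutation pair lists.
    clinical_path :
        Optional clinical TSV with a ``sample_id`` column.
    max_missing_frac :
        Features missing in more than this fraction of samples are dropped;
        remaining missing values are median-imputed per feature.

    Samples are intersected across all inputs and ordered by sorted sample
    ID so downstream results do not depend on file order. Zero-variance
    features are dropped with a logged count.
    """
    raw: list[tuple[str, str, pd.DataFrame]] = []
    for path, kind, name in layer_files:
        path = Path(path)
        if kind == "binary" and _looks_like_pairs(path):
            df = _load_mutation_pairs(path)
        else:
            df = read_matrix(path)
        raw.append((name, kind, df))

    clinical = None
    if clinical_path is not None:
        clinical = pd.read_csv(clinical_path, sep=_detect_sep(Path(clinical_path)))
        clinical = clinical.set_index(clinical.columns[0])
        clinical.index = clinical.index.astype(str)

    common: set[str] | None = None
    for _, _, df in raw:
        common = set(df.columns) if common is None else common & set(df.columns)
    if clinical is not None:
        common = common & set(clinical.index)
    if not common:
        raise ValueError("empty sample intersection across layers/clinical table")
    order = sorted(common)

    layers = []
    for name, kind, df in raw:
        df = df[order]
        n_missing = int(df.isna().any(axis=1).sum())
        too_missing = df.isna().mean(axis=1) > max_missing_frac
        if too_missing.any():
            logger.info("layer %s: dropped %d features missing in >%.0f%% of samples",
                        name, int(too_missing.sum()), 100 * max_missing_frac)
            df = df.loc[~too_missing]
        if df.isna().any().any():
            med = df.median(axis=1)
            df = df.apply(lambda row: row.fillna(med[row.name]), axis=1)
            logger.info("layer %s: median-imputed %d features with missing values", name, n_missing)
        const = df.std(axis=1) == 0
        if const.any():
            logger.info("layer %s: dropped %d zero-variance features", name, int(const.sum()))
            df = df.loc[~const]
        if kind == "binary":
            df = df.round().clip(0, 1)
        layers.append(OmicsLayer(name=name, kind=kind, values=df))

    if clinical is not None:
        clinical = clinical.loc[order]
    return MultiOmicsDataset(layers=layers, clinical=clinical)
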