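"""Reading, validating, filtering and binarizing signature data.

The drug side of the screen is an L1000-style Level 5 matrix: replicate-averaged
Z-scores for each gene in each perturbation signature, with per-signature
metadata (compound, cell line, dose, time, TAS).  The reference side is a
differential-expression profile (log2 fold change + p-value per gene).  Both
are reduced to trinary calls in {-1, 0, +1} before any scoring:

* drug signatures: ``|Z| >= z_threshold`` (boundary inclusive),
* reference profile: ``|log2FC| > fc_threshold`` and ``p <= p_threshold``
  (fold-change boundary strict by default; see :func:`build_reference`).

Supported on-disk formats are GCT 1.3 text, a TSV dialect (genes x signatures
with a sidecar metadata TSV), GMT gene-set collections, and a three-column
reference-profile TSV.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptyScreenError, ParseError, ValidationError

logger = logging.getLogger(__name__)

#: metadata columns every SignatureMatrix carries (absent fields hold NA)
META_COLUMNS = ["compound_id", "cell_line", "dose", "time", "tas"]

#: string marker used for absent metadata in text files
MISSING = "NA"

_DOSE_UNIT = {"um": "uM", "µm": "uM", "μm": "uM", "nm": "nM", "mm": "mM", "m": "M"}
_TIME_UNIT = {"h": "h", "hr": "h", "hrs": "h", "hour": "h", "hours": "h",
              "min": "min", "m": "min", "s": "s"}


def canonicalize_dose(dose: object) -> object:
    """Normalize a dose string to ``<number><unit>`` (e.g. ``10 µM`` -> ``10uM``)."""
    if dose is None or (isinstance(dose, float) and np.isnan(dose)):
        return pd.NA
    s = str(dose).strip().lower().replace(" ", "")
    m = re.fullmatch(r"([0-9.]+)(µm|μm|um|nm|mm|m)?", s)
    if m is None:
        return str(dose).strip()
    num, unit = m.group(1), m.group(2)
    unit = _DOSE_UNIT.get(unit, "") if unit else ""
    return f"{num}{unit}"


def canonicalize_time(time: object) -> object:
    """Normalize a time string to ``<number><unit>`` (e.g. ``24 hr`` -> ``24h``)."""
    if time is None or (isinstance(time, float) and np.isnan(time)):
        return pd.NA
    s = str(time).strip().lower().replace(" ", "")
    m = re.fullmatch(r"([0-9.]+)(hours|hour|hrs|hr|h|min|s)?", s)
    if m is None:
        return str(time).strip()
    num, unit = m.group(1), m.group(2)
    unit = _TIME_UNIT.get(unit, "") if unit else ""
    return f"{num}{unit}"


def _check_unique(ids: Iterable[str], kind: str) -> None:
    seen: dict[str, int] = {}
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValidationError(f"duplicate {kind} ids: {dups}")


@dataclass
class SignatureMatrix:
    """Genes x signatures matrix of replicate-averaged Z-scores plus metadata.

    ``values`` is a DataFrame indexed by gene id with one column per signature;
    ``meta`` is indexed by signature id with columns :data:`META_COLUMNS`.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "signature")
        if len(self.meta) != self.values.shape[1]:
            raise ValidationError(
                f"meta has {len(self.meta)} rows for {self.values.shape[1]} signatures"
            )
        if not self.meta.index.equals(self.values.columns):
            self.meta = self.meta.reindex(self.values.columns)
            if self.meta.isna().all(axis=1).any():
                raise ValidationError("meta index does not match signature ids")
        for col in META_COLUMNS:
            if col not in self.meta.columns:
                self.meta[col] = pd.NA
        # plain float() round-trips repr() exactly (pd.to_numeric's fast
        # parser does not), which the GCT writer/reader contract relies on
        tas = self.meta["tas"].map(lambda v: np.nan if pd.isna(v) else float(v))
        bad = tas.dropna()[(tas.dropna() < 0) | (tas.dropna() > 1)]
        if len(bad):
            raise ValidationError(f"TAS outside [0,1] for {list(bad.index)}")
        self.meta = self.meta.copy()
        self.meta["tas"] = tas

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def signature_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Sequence[str]) -> "SignatureMatrix":
        return SignatureMatrix(self.values.loc[list(genes)], self.meta.copy())


@dataclass
class BinarizedProfile:
    """Per-gene trinary calls over a fixed gene universe."""

    gene_universe: pd.Index
    values: np.ndarray
    signature_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if len(self.values) != len(self.gene_universe):
            raise ValidationError("calls and gene universe differ in length")
        if not np.isin(self.values, (-1, 0, 1)).all():
            raise ValidationError("calls must lie in {-1, 0, +1}")

    @property
    def calls(self) -> dict[str, int]:
        return dict(zip(self.gene_universe, (int(v) for v in self.values)))

    @property
    def nonzero_genes(self) -> set[str]:
        return set(self.gene_universe[self.values != 0])


@dataclass
class ReferenceProfile:
    """Binarized target profile with its fold-change / p-value provenance."""

    gene_universe: pd.Index
    values: np.ndarray
    fc: pd.Series
    pval: pd.Series
    thresholds: tuple[float, float]
    name: str = "reference"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if len(self.values) != len(self.gene_universe):
            raise ValidationError("calls and gene universe differ in length")
        if not np.isin(self.values, (-1, 0, 1)).all():
            raise ValidationError("calls must lie in {-1, 0, +1}")

    @property
    def calls(self) -> dict[str, int]:
        return dict(zip(self.gene_universe, (int(v) for v in self.values)))

    @property
    def deg_set(self) -> set[str]:
        return set(self.gene_universe[self.values != 0])

    @property
    def n_deg(self) -> int:
        return int(np.count_nonzero(self.values))

    def align(self, genes: Sequence[str], name: str | None = None) -> "ReferenceProfile":
        """Restrict the profile to the genes shared with ``genes``.

        The DEG count |A| is recomputed within the intersection; dropped
        reference DEGs are logged (scoring on unmeasured genes is undefined).
        """
        shared = [g for g in genes if g in set(self.gene_universe)]
        if not shared:
            raise EmptyScreenError("no genes shared between reference and matrix")
        idx = pd.Index(shared)
        pos = self.gene_universe.get_indexer(idx)
        vals = self.values[pos]
        dropped = self.n_deg - int(np.count_nonzero(vals))
        if dropped:
            logger.info("reference alignment dropped %d DEGs not in the matrix", dropped)
        return ReferenceProfile(
            idx, vals, self.fc.reindex(idx), self.pval.reindex(idx),
            self.thresholds, name or self.name,
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), optionally tagged with a direction."""

    sets: dict[str, set[str]]
    direction_tag: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


# ---------------------------------------------------------------------------
# GCT 1.3 text
# ---------------------------------------------------------------------------

def read_gct(path: str | Path) -> SignatureMatrix:
    """Read a GCT 1.3 text file into a :class:`SignatureMatrix`.

    Column metadata named after :data:`META_COLUMNS` is recognised; other
    column-metadata rows are ignored.  Absent metadata fields are set to NA.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("#1."):
        raise ParseError(f"{path}: line 1 is not a GCT version line: {lines[:1]}")
    dims = lines[1].split("\t")
    if len(dims) not in (2, 4):
        raise ParseError(f"{path}: malformed dimension line (line 2): {lines[1]!r}")
    try:
        nums = [int(x) for x in dims]
    except ValueError as exc:
        raise ParseError(f"{path}: malformed dimension line (line 2): {lines[1]!r}") from exc
    nrow, ncol = nums[0], nums[1]
    nrowmeta = nums[2] if len(nums) == 4 else 0
    ncolmeta = nums[3] if len(nums) == 4 else 0
    header = lines[2].split("\t")
    sig_ids = header[1 + nrowmeta:]
    if len(sig_ids) != ncol:
        raise ParseError(f"{path}: header row announces {len(sig_ids)} signatures, expected {ncol}")
    meta_rows: dict[str, list[str]] = {}
    for i in range(ncolmeta):
        parts = lines[3 + i].split("\t")
        meta_rows[parts[0]] = parts[1 + nrowmeta:]
    genes, data = [], []
    for i, line in enumerate(lines[3 + ncolmeta: 3 + ncolmeta + nrow]):
        parts = line.split("\t")
        if len(parts) != 1 + nrowmeta + ncol:
            raise ParseError(f"{path}: data line {3 + ncolmeta + i + 1} has {len(parts)} fields")
        genes.append(parts[0])
        data.append([float(x) for x in parts[1 + nrowmeta:]])
    values = pd.DataFrame(np.asarray(data, dtype=float), index=genes, columns=sig_ids)
    meta = pd.DataFrame(index=pd.Index(sig_ids, name="signature_id"))
    for col in META_COLUMNS:
        if col in meta_rows:
            raw = [pd.NA if v == MISSING else v for v in meta_rows[col]]
            meta[col] = raw
        else:
            meta[col] = pd.NA
    return SignatureMatrix(values, meta)


def write_gct(matrix: SignatureMatrix, path: str | Path) -> None:
    """Write a :class:`SignatureMatrix` as GCT 1.3 text (round-trips bit-exactly)."""
    path = Path(path)
    nrow, ncol = matrix.shape
    with open(path, "w") as fh:
        fh.write("#1.3\n")
        fh.write(f"{nrow}\t{ncol}\t0\t{len(META_COLUMNS)}\n")
        fh.write("id\t" + "\t".join(matrix.signature_ids) + "\n")
        for col in META_COLUMNS:
            vals = []
            for v in matrix.meta[col]:
                if pd.isna(v):
                    vals.append(MISSING)
                elif col == "tas":
                    vals.append(repr(float(v)))
                else:
                    vals.append(str(v))
            fh.write(col + "\t" + "\t".join(vals) + "\n")
        arr = matrix.values.to_numpy()
        for i, gene in enumerate(matrix.gene_ids):
            fh.write(gene + "\t" + "\t".join(repr(float(x)) for x in arr[i]) + "\n")


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def read_tsv_matrix(path: str | Path, meta_path: str | Path | None = None) -> SignatureMatrix:
    """Read a genes x signatures TSV (first column gene id) plus optional sidecar
    metadata TSV keyed by ``signature_id``."""
    values = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col="signature_id", comment="#")
    else:
        meta = pd.DataFrame(index=values.columns)
    return SignatureMatrix(values.astype(float), meta)


def write_tsv_matrix(matrix: SignatureMatrix, path: str | Path,
                     meta_path: str | Path | None = None) -> None:
    matrix.values.rename_axis("gene").to_csv(path, sep="\t")
    if meta_path is not None:
        matrix.meta.rename_axis("signature_id").to_csv(meta_path, sep="\t")


def read_reference_tsv(path: str | Path) -> tuple[pd.Series, pd.Series]:
    """Read a reference-profile TSV with columns gene, log2fc, pval."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "log2fc", "pval"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    df = df.set_index("gene")
    return df["log2fc"].astype(float), df["pval"].astype(float)


def write_reference_tsv(fc: pd.Series, pval: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"gene": fc.index, "log2fc": fc.values,
                  "pval": pval.reindex(fc.index).values}).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name TAB description TAB gene...``."""
    sets: dict[str, set[str]] = {}
    tags: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno} has {len(parts)} fields (need >= 3)")
            name = parts[0]
            if name in sets:
                raise ValidationError(f"{path}: duplicate set name {name!r} at line {lineno}")
            genes = {g for g in parts[2:] if g}
            if not genes:
                raise ParseError(f"{path}: line {lineno} lists no genes")
            sets[name] = genes
            if parts[1] and parts[1] != MISSING:
                tags[name] = parts[1]
    return GeneSetCollection(sets, tags)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            desc = collection.direction_tag.get(name, MISSING)
            fh.write(name + "\t" + desc + "\t" + "\t".join(sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# Filtering and binarization
# ---------------------------------------------------------------------------

def filter_signatures(matrix: SignatureMatrix, dose: str | None = None,
                      time: str | None = None, tas_min: float | None = None,
                      ) -> SignatureMatrix:
    """Keep signatures at a fixed dose and time with TAS >= ``tas_min``.

    Dose and time are matched by exact equality after unit canonicalization
    (``10 µM``, ``10um`` and ``10uM`` all match).  Signatures with missing TAS
    are excluded when a TAS filter is requested (logged) and retained
    otherwise.  Raises :class:`EmptyScreenError` when nothing survives.
    """
    keep = pd.Series(True, index=matrix.signature_ids)
    if dose is not None:
        want = canonicalize_dose(dose)
        got = matrix.meta["dose"].map(canonicalize_dose)
        mask = got == want
        logger.info("dose filter %s: kept %d / dropped %d", want, mask.sum(), (~mask).sum())
        keep &= mask
    if time is not None:
        want = canonicalize_time(time)
        got = matrix.meta["time"].map(canonicalize_time)
        mask = got == want
        logger.info("time filter %s: kept %d / dropped %d", want, mask.sum(), (~mask).sum())
        keep &= mask
    if tas_min is not None:
        tas = matrix.meta["tas"]
        missing = tas.isna()
        if missing.any():
            logger.warning("%d signatures lack TAS and are excluded by the TAS filter",
                           int(missing.sum()))
        mask = tas.ge(tas_min).fillna(False)
        logger.info("TAS >= %s: kept %d / dropped %d", tas_min, mask.sum(), (~mask).sum())
        keep &= mask
    if not keep.any():
        raise EmptyScreenError("filter removed every signature; screen cannot proceed")
    kept_ids = matrix.signature_ids[keep.to_numpy()]
    return SignatureMatrix(matrix.values.loc[:, kept_ids], matrix.meta.loc[kept_ids])


def binarize_values(values: pd.DataFrame | np.ndarray, z_threshold: float = 1.0) -> np.ndarray:
    """Trinarize a Z-score array: ``|z| >= threshold`` -> sign(z), else 0."""
    if z_threshold <= 0:
        raise ValidationError("z_threshold must be positive")
    arr = np.asarray(values, dtype=float)
    if not np.isfinite(arr).all():
        bad = np.argwhere(~np.isfinite(arr))
        r, c = bad[0]
        if isinstance(values, pd.DataFrame):
            raise ValidationError(
                f"non-finite Z-score at gene {values.index[r]!r}, signature {values.columns[c]!r}")
        raise ValidationError(f"non-finite Z-score at position {(int(r), int(c))}")
    out = np.zeros(arr.shape, dtype=np.int8)
    out[arr >= z_threshold] = 1
    out[arr <= -z_threshold] = -1
    return out


def binarize_zscores(matrix: SignatureMatrix, z_threshold: float = 1.0) -> list[BinarizedProfile]:
    """Binarize every signature column; the gene universe is the matrix's gene axis."""
    calls = binarize_values(matrix.values, z_threshold)
    return [BinarizedProfile(matrix.gene_ids, calls[:, j], sig)
            for j, sig in enumerate(matrix.signature_ids)]


def build_reference(fc: Mapping[str, float] | pd.Series,
                    pval: Mapping[str, float] | pd.Series,
                    fc_threshold: float = 1.0, p_threshold: float = 0.05,
                    inclusive: bool = False, name: str = "reference") -> ReferenceProfile:
    """Build the binarized reference (target) profile from DE statistics.

    A gene is a DEG when ``|log2FC| > fc_threshold`` (``>=`` with
    ``inclusive=True``) and ``p <= p_threshold``; its call is the sign of the
    fold change, all other genes are 0.
    """
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValidationError("thresholds must be positive")
    fc = pd.Series(fc, dtype=float) if not isinstance(fc, pd.Series) else fc.astype(float)
    pval = pd.Series(pval, dtype=float) if not isinstance(pval, pd.Series) else pval.astype(float)
    missing = fc.index.difference(pval.index)
    if len(missing):
        raise ValidationError(f"genes missing a p-value: {sorted(missing)[:5]}")
    pval = pval.reindex(fc.index)
    if ((pval < 0) | (pval > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    mag = fc.abs().to_numpy()
    passes_fc = mag >= fc_threshold if inclusive else mag > fc_threshold
    deg = passes_fc & (pval.to_numpy() <= p_threshold)
    calls = np.where(deg, np.sign(fc.to_numpy()), 0).astype(np.int8)
    if not deg.any():
        logger.warning("reference profile has no DEGs (|A| = 0): unusable for scoring")
    return ReferenceProfile(fc.index, calls, fc, pval, (fc_threshold, p_threshold), name)
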