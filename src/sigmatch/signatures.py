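"""Signed-significance gene signatures.

A *signature* summarises one differential-expression contrast as a single
number per gene: ``-log10(p) * sign(direction of change)``.  Positive values
mean the gene is up-regulated in the contrast, negative values down-regulated,
and the magnitude carries the statistical evidence.  This formatting lets
heterogeneous microarray and RNA-seq studies be compared on one scale.

The module owns loading/writing the on-disk TSV format, gene-symbol
harmonisation (uppercasing, optional ortholog remapping), manifests listing
many signature files, and extraction of the top-*n* up- and down-regulated
gene sets within the gene universe shared by two signatures.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    EmptySignatureError,
    FormatError,
    InvalidInputError,
    NoOverlapError,
)

__all__ = [
    "SIGNIFICANCE_CAP",
    "GeneSignature",
    "RankedSets",
    "Manifest",
    "signed_significance",
    "load_signature",
    "write_signature",
    "load_ortholog_map",
    "load_manifest",
    "top_ranked_sets",
]

logger = logging.getLogger(__name__)

#: Cap on |signed significance|.  -log10 of the smallest positive double is
#: ~323.6; capping slightly below keeps every stored value finite and makes
#: underflowed p-values representable.
SIGNIFICANCE_CAP = 320.0

#: Column names of the on-disk signature TSV.
SIGNATURE_COLUMNS = ("gene", "signed_log10_p")

#: Required manifest columns.
MANIFEST_COLUMNS = ("id", "path", "species", "sex", "tissue", "accession", "group")


def signed_significance(p, direction: int, cap: float = SIGNIFICANCE_CAP) -> float:
    """Convert a p-value and a direction of change into a signed significance.

    Parameters
    ----------
    p : real number in (0, 1]
        The p-value of the contrast for one gene.  ``Decimal`` and
        ``fractions.Fraction`` inputs are accepted so p-values below the
        double-precision underflow threshold still map to the cap rather
        than erroring.
    direction : {+1, -1, 0}
        Sign of the fold change (+1 up, -1 down, 0 no direction).
    cap : float
        Maximum magnitude of the result.

    Returns
    -------
    float
        ``-log10(p) * direction``, clipped to ``[-cap, +cap]``.
    """
    if direction not in (-1, 0, 1):
        raise InvalidInputError(f"direction must be one of -1, 0, +1; got {direction!r}")
    if isinstance(p, Decimal):
        if not (0 < p <= 1):
            raise InvalidInputError(f"p must lie in (0, 1]; got {p}")
        neglog = -float(p.log10())
    else:
        pf = float(p)
        if pf == 0.0 and _exactly_positive(p):
            neglog = math.inf  # positive exact value below float underflow
        elif not (0.0 < pf <= 1.0):
            raise InvalidInputError(f"p must lie in (0, 1]; got {p!r}")
        else:
            neglog = -math.log10(pf)
    return float(min(neglog, cap)) * direction


def _exactly_positive(p) -> bool:
    try:
        return p > 0 and float(p) == 0.0
    except TypeError:  # pragma: no cover - exotic numeric types
        return False


@dataclass
class GeneSignature:
    """One dataset's signed-significance values keyed by gene symbol.

    Parameters
    ----------
    dataset_id : str
        Unique identifier of the dataset (e.g. ``"m142"``).
    values : dict[str, float]
        Map from uppercase gene symbol to signed significance.
    species : str
        Source species, free text (``"mouse"``, ``"human"``, ...).
    metadata : dict
        Optional annotations (sex, tissue, GEO accession, group, ...).
    """

    dataset_id: str
    values: dict[str, float]
    species: str = "unknown"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [g for g, v in self.values.items() if not math.isfinite(v)]
        if bad:
            raise InvalidInputError(
                f"signature {self.dataset_id!r} has non-finite values for {bad[:5]}"
            )

    def __len__(self) -> int:
        return len(self.values)

    def __contains__(self, gene: str) -> bool:
        return gene in self.values

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.values)

    def to_series(self) -> pd.Series:
        """Values as a pandas Series indexed by gene symbol, sorted by symbol."""
        s = pd.Series(self.values, name=self.dataset_id, dtype=float)
        return s.sort_index()

    @classmethod
    def from_series(
        cls, s: pd.Series, dataset_id: str, species: str = "unknown", metadata: dict | None = None
    ) -> "GeneSignature":
        return cls(
            dataset_id=dataset_id,
            values={str(g).strip().upper(): float(v) for g, v in s.items()},
            species=species,
            metadata=dict(metadata or {}),
        )

    def flipped(self, dataset_id: str | None = None) -> "GeneSignature":
        """Sign-reversed copy (every up becomes down and vice versa)."""
        return GeneSignature(
            dataset_id=dataset_id or f"{self.dataset_id}-flipped",
            values={g: -v for g, v in self.values.items()},
            species=self.species,
            metadata=dict(self.metadata),
        )


@dataclass(frozen=True)
class RankedSets:
    """Top-ranked up and down gene sets of one signature in a shared universe.

    ``up`` holds the at-most-``n_top`` genes with the largest positive signed
    significance (most significant first); ``down`` the most negative.  Zero
    values carry no direction and belong to neither set.  Ties are broken by
    ascending gene symbol so the extraction is deterministic.
    """

    universe: frozenset[str]
    up: tuple[str, ...]
    down: tuple[str, ...]
    n_top: int

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise InvalidInputError("up and down sets overlap")
        if not (set(self.up) | set(self.down)) <= self.universe:
            raise InvalidInputError("ranked sets outside universe")


def top_ranked_sets(
    a: GeneSignature, b: GeneSignature, n_top: int = 1000
) -> tuple[RankedSets, RankedSets]:
    """Extract the top-``n_top`` up/down gene sets of ``a`` and ``b`` on their
    shared gene universe.

    Both signatures are restricted to the intersection of their gene sets so
    that the later hypergeometric tests draw from one well-defined universe.
    Sets may be shorter than ``n_top`` when fewer signed genes exist.
    """
    if n_top < 1:
        raise InvalidInputError(f"n_top must be >= 1; got {n_top}")
    universe = a.genes & b.genes
    if not universe:
        raise NoOverlapError(
            f"signatures {a.dataset_id!r} and {b.dataset_id!r} share no genes"
        )
    return (_ranked_sets(a, universe, n_top), _ranked_sets(b, universe, n_top))


def _ranked_sets(sig: GeneSignature, universe: frozenset[str], n_top: int) -> RankedSets:
    vals = sig.values
    up = sorted((g for g in universe if vals[g] > 0), key=lambda g: (-vals[g], g))
    down = sorted((g for g in universe if vals[g] < 0), key=lambda g: (vals[g], g))
    return RankedSets(universe=universe, up=tuple(up[:n_top]), down=tuple(down[:n_top]), n_top=n_top)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_signature(
    path,
    dataset_id: str | None = None,
    species: str = "unknown",
    metadata: dict | None = None,
    ortholog_map: dict[str, str] | None = None,
) -> GeneSignature:
    """Load a two-column (gene, signed -log10 p) TSV into a :class:`GeneSignature`.

    Gene symbols are stripped and uppercased (the default cross-species
    harmonisation: mouse ``Bdnf`` -> ``BDNF``); an explicit ``ortholog_map``
    overrides individual symbols before uppercasing.  Rows with non-finite or
    unparseable values are dropped with a logged count, and duplicate symbols
    collapse to the entry with the largest absolute value (the most
    significant probe).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str, comment="#")
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as a tab-separated table: {exc}") from exc
    if df.shape[1] < 2:
        raise FormatError(
            f"{path}: expected >= 2 columns (gene, signed value); got {df.shape[1]}"
        )
    genes = df.iloc[:, 0].astype(str).str.strip()
    if ortholog_map:
        genes = genes.map(lambda g: ortholog_map.get(g, ortholog_map.get(g.upper(), g)))
    genes = genes.str.upper()
    vals = pd.to_numeric(df.iloc[:, 1], errors="coerce")

    keep = np.isfinite(vals.to_numpy(dtype=float, na_value=np.nan)) & (genes != "")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: dropped %d rows with non-finite or missing entries", path, n_dropped)
    tab = pd.DataFrame({"gene": genes[keep], "value": vals[keep].astype(float)})
    if tab.empty:
        raise EmptySignatureError(f"{path}: no usable rows after filtering")

    n_dup = int(tab["gene"].duplicated().sum())
    if n_dup:
        logger.info("%s: collapsed %d duplicate gene symbols (kept max |value|)", path, n_dup)
        # deterministic collapse: largest |value|, then largest value, per symbol
        tab = tab.sort_values(
            by=["gene", "value"],
            key=lambda s: s.abs() if s.name == "value" else s,
            ascending=[True, False],
        )
        tab = tab.drop_duplicates("gene", keep="first")

    values = dict(zip(tab["gene"], np.clip(tab["value"], -SIGNIFICANCE_CAP, SIGNIFICANCE_CAP)))
    return GeneSignature(
        dataset_id=dataset_id or path.stem,
        values={g: float(v) for g, v in values.items()},
        species=species,
        metadata=dict(metadata or {}),
    )


def write_signature(sig: GeneSignature, path) -> Path:
    """Write a signature as the standard two-column TSV (genes sorted)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    s = sig.to_series()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(SIGNATURE_COLUMNS) + "\n")
        for g, v in s.items():
            fh.write(f"{g}\t{v!r}\n")
    return path


def load_ortholog_map(path) -> dict[str, str]:
    """Load a two-column (source symbol, target symbol) TSV ortholog map."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except Exception as exc:
        raise FormatError(f"cannot parse ortholog map {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: ortholog map needs two columns")
    return {
        str(src).strip(): str(dst).strip().upper()
        for src, dst in zip(df.iloc[:, 0], df.iloc[:, 1])
        if pd.notna(src) and pd.notna(dst)
    }


@dataclass
class Manifest:
    """Table of signature files to analyse: one row per dataset.

    Columns: id, path, species, sex, tissue, accession, group.  ``group`` is
    ``"model"`` for candidate model datasets, ``"human"`` for individual
    human case/control datasets feeding the portrait, or ``"portrait"`` for
    a prebuilt consensus signature used directly as the reference.
    """

    frame: pd.DataFrame
    root: Path

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"manifest missing columns: {missing}")
        ids = self.frame["id"]
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise FormatError(f"manifest has duplicate dataset ids: {dups}")
        bad_group = set(self.frame["group"]) - {"model", "human", "portrait"}
        if bad_group:
            raise FormatError(f"manifest has unknown group labels: {sorted(bad_group)}")

    def resolve(self, row) -> Path:
        p = Path(row["path"])
        return p if p.is_absolute() else self.root / p

    def rows(self, group: str | None = None):
        frame = self.frame if group is None else self.frame[self.frame["group"] == group]
        return frame.to_dict("records")

    def load_group(self, group: str) -> list[GeneSignature]:
        """Load all signatures of one group, fail-fast on the offending row."""
        out = []
        for row in self.rows(group):
            path = self.resolve(row)
            if not path.exists():
                raise FormatError(f"manifest row {row['id']!r}: file not found: {path}")
            meta = {k: row[k] for k in ("sex", "tissue", "accession", "group") if pd.notna(row[k])}
            out.append(
                load_signature(path, dataset_id=row["id"], species=str(row["species"]), metadata=meta)
            )
        return out


def load_manifest(path) -> Manifest:
    """Load and validate a manifest CSV (id,path,species,sex,tissue,accession,group)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:
        raise FormatError(f"cannot parse manifest {path}: {exc}") from exc
    return Manifest(frame=df, root=path.parent)
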