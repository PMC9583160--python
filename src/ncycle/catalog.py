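"""Nitrogen-cycle gene catalog and tabular I/O.

The catalog maps KEGG Orthology (KO) terms to gene symbols, the multi-subunit
protein (operon) they encode, and the nitrogen-cycle pathways they participate
in (nitrogen fixation, nitrification, denitrification, dissimilatory and
assimilatory nitrate reduction, anammox). Metagenome annotations are consumed
at KO resolution: a KO such as K00370 covers narG/narZ/nxrA indistinguishably,
so all downstream metrics are per-KO and gene symbols are reported as aliases.

Gene-record input mirrors per-metagenome annotation exports: one TSV per
sample with columns ``gene_id``, ``ko``, ``estimated_copy``, tied to sample
identifiers through a manifest CSV (``sample_id,path``). Sample metadata is a
CSV with ``sample_id``, planar ``x``/``y`` coordinates (meters; inputs must be
pre-projected) and numeric biogeochemical covariates.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger("ncycle")

KO_PATTERN = re.compile(r"^K\d{5}$")

#: Canonical pathway names used throughout the package.
PATHWAYS = frozenset(
    {"nitrogen fixation", "nitrification", "denitrification", "DNR", "ANR", "anammox"}
)


class CatalogError(RuntimeError):
    """Raised when the packaged catalog resource is missing or corrupt."""


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class CatalogEntry:
    """One KO term of the nitrogen-cycle catalog.

    Attributes
    ----------
    protein:
        Name of the protein complex (operon) the KO belongs to, e.g.
        ``"NifDKH"`` or ``"NarGHI/NxrAB"``.
    gene_symbols:
        Gene aliases sharing the KO, e.g. ``("narG", "narZ", "nxrA")``.
    ko:
        KO code of the form ``K`` + five digits.
    pathways:
        Non-empty subset of :data:`PATHWAYS`.
    """

    protein: str
    gene_symbols: tuple[str, ...]
    ko: str
    pathways: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not KO_PATTERN.match(self.ko):
            raise CatalogError(f"malformed KO code {self.ko!r}")
        if not self.pathways:
            raise CatalogError(f"entry {self.ko} has no pathway membership")
        unknown = self.pathways - PATHWAYS
        if unknown:
            raise CatalogError(f"entry {self.ko}: unknown pathways {sorted(unknown)}")


class GeneCatalog:
    """Immutable lookup structure over the nitrogen-cycle KO catalog."""

    def __init__(self, entries: Iterable[CatalogEntry]):
        self.entries: tuple[CatalogEntry, ...] = tuple(entries)
        self._by_ko: dict[str, CatalogEntry] = {}
        for e in self.entries:
            if e.ko in self._by_ko:
                raise CatalogError(f"duplicate KO {e.ko} in catalog")
            self._by_ko[e.ko] = e

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, ko: str) -> bool:
        return ko in self._by_ko

    @property
    def kos(self) -> tuple[str, ...]:
        return tuple(e.ko for e in self.entries)

    @property
    def proteins(self) -> tuple[str, ...]:
        """Protein (operon) names in catalog order, deduplicated."""
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.protein, None)
        return tuple(seen)

    def lookup(self, ko: str) -> CatalogEntry:
        try:
            return self._by_ko[ko]
        except KeyError:
            raise KeyError(f"KO {ko!r} is not in the nitrogen-cycle catalog") from None

    def members_of_protein(self, protein: str) -> frozenset[str]:
        """KO codes of all subunits of an operon/protein complex."""
        members = frozenset(e.ko for e in self.entries if e.protein == protein)
        if not members:
            raise KeyError(f"protein {protein!r} is not in the catalog")
        return members

    def kos_in_pathway(self, pathway: str) -> frozenset[str]:
        if pathway not in PATHWAYS:
            raise KeyError(f"unknown pathway {pathway!r}")
        return frozenset(e.ko for e in self.entries if pathway in e.pathways)

    def gene_label(self, ko: str) -> str:
        """Comma-joined gene aliases for a KO (for report columns)."""
        return ", ".join(self.lookup(ko).gene_symbols)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein": [e.protein for e in self.entries],
                "gene": [", ".join(e.gene_symbols) for e in self.entries],
                "ko": [e.ko for e in self.entries],
                "pathways": [";".join(sorted(e.pathways)) for e in self.entries],
            }
        )


def _parse_catalog(text: str) -> GeneCatalog:
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
    required = {"protein", "gene", "ko", "pathways"}
    missing = required - set(df.columns)
    if missing:
        raise CatalogError(f"catalog resource missing columns {sorted(missing)}")
    entries = []
    for row in df.itertuples(index=False):
        entries.append(
            CatalogEntry(
                protein=row.protein.strip(),
                gene_symbols=tuple(g.strip() for g in row.gene.split(",")),
                ko=row.ko.strip(),
                pathways=frozenset(p.strip() for p in row.pathways.split(";")),
            )
        )
    return GeneCatalog(entries)


def load_catalog() -> GeneCatalog:
    """Load the packaged nitrogen-cycle KO catalog.

    Returns every catalog entry; lookups by KO, protein and pathway are all
    backed by the same entry set.
    """
    try:
        text = (
            resources.files("ncycle").joinpath("data/nitrogen_catalog.tsv").read_text()
        )
    except (FileNotFoundError, ModuleNotFoundError) as exc:  # pragma: no cover
        raise CatalogError("packaged catalog resource is missing") from exc
    return _parse_catalog(text)


def write_catalog(catalog: GeneCatalog, path: str | Path) -> None:
    """Serialize a catalog to TSV (round-trips through :func:`_parse_catalog`)."""
    catalog.to_frame().to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path) -> GeneCatalog:
    return _parse_catalog(Path(path).read_text())


# ---------------------------------------------------------------------------
# Gene-record tables
# ---------------------------------------------------------------------------

GENE_RECORD_COLUMNS = ("gene_id", "ko", "estimated_copy")


def read_gene_records(
    path: str | Path,
    sample_id: str,
    catalog: GeneCatalog,
) -> pd.DataFrame:
    """Read one sample's gene-record TSV, keeping only catalog KOs.

    Parameters
    ----------
    path:
        TSV with header columns ``gene_id``, ``ko``, ``estimated_copy``.
    sample_id:
        Sample the file belongs to.
    catalog:
        Records whose KO is absent from the catalog are dropped (counted in
        the log, never passed downstream).

    Returns
    -------
    DataFrame with columns ``sample_id, gene_id, ko, estimated_copy``.

    Raises
    ------
    ValidationError
        On a missing required column, a negative or non-numeric
        ``estimated_copy`` (the offending row number is named), or a
        duplicated ``(sample_id, gene_id)`` pair.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "ko": str})
    missing = set(GENE_RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s) {sorted(missing)}"
        )
    df = df.loc[:, list(GENE_RECORD_COLUMNS)].copy()
    copies = pd.to_numeric(df["estimated_copy"], errors="coerce")
    bad = df.index[copies.isna() & df["estimated_copy"].notna()]
    if len(bad):
        raise ValidationError(
            f"{path}: non-numeric estimated_copy at data row {bad[0] + 1}"
        )
    neg = df.index[copies <= 0]
    if len(neg):
        raise ValidationError(
            f"{path}: estimated_copy must be > 0, violated at data row {neg[0] + 1}"
        )
    df["estimated_copy"] = copies.astype(float)
    dup = df["gene_id"].duplicated()
    if dup.any():
        raise ValidationError(
            f"{path}: duplicated gene_id {df.loc[dup.idxmax(), 'gene_id']!r} "
            f"within sample {sample_id!r}"
        )
    n_raw = len(df)
    df = df[df["ko"].isin(set(catalog.kos))].copy()
    logger.info(
        "sample %s: %d/%d records retained after catalog filtering",
        sample_id,
        len(df),
        n_raw,
    )
    df.insert(0, "sample_id", sample_id)
    return df.reset_index(drop=True)


def read_manifest(path: str | Path) -> dict[str, Path]:
    """Read a ``sample_id,path`` manifest CSV; paths resolve relative to it."""
    base = Path(path).parent
    df = pd.read_csv(path, dtype=str)
    missing = {"sample_id", "path"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: manifest missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample_id in manifest")
    return {row.sample_id: base / row.path for row in df.itertuples(index=False)}


def read_all_gene_records(
    manifest: Mapping[str, Path] | str | Path, catalog: GeneCatalog
) -> pd.DataFrame:
    """Concatenate per-sample gene-record tables listed in a manifest."""
    if not isinstance(manifest, Mapping):
        manifest = read_manifest(manifest)
    parts = [read_gene_records(p, sid, catalog) for sid, p in manifest.items()]
    if not parts:
        return pd.DataFrame(columns=["sample_id", *GENE_RECORD_COLUMNS])
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Environmental metadata
# ---------------------------------------------------------------------------


def read_env_table(
    path: str | Path, gene_samples: Iterable[str] | None = None
) -> pd.DataFrame:
    """Read the sample metadata CSV.

    First column must be ``sample_id``; ``x`` and ``y`` hold projected planar
    coordinates; every remaining column is coerced to float, with blank cells
    becoming NaN (explicit missing, never zero).

    When ``gene_samples`` is given, metadata samples with no gene data are
    reported as orphans in the log (a warning, not an error).
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'sample_id'")
    for col in ("x", "y"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing coordinate column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate sample_id {dup!r}")
    for col in df.columns:
        if col == "sample_id":
            continue
        df[col] = pd.to_numeric(df[col], errors="coerce")
    coords = df[["x", "y"]].apply(tuple, axis=1)
    if coords.duplicated().any():
        raise ValidationError(f"{path}: coordinate pairs must be distinct")
    df = df.set_index("sample_id")
    if gene_samples is not None:
        orphans = sorted(set(df.index) - set(gene_samples))
        if orphans:
            logger.warning(
                "metadata samples without gene records: %s", ", ".join(orphans)
            )
    logger.info("metadata: %d samples, %d variables", len(df), df.shape[1] - 2)
    return df
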