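"""Per-sample gene statistics and operon-completeness presence calls.

For each sample and each catalog KO three statistics are computed from the
annotation records:

* **abundance** — sum of the Estimated Copy values of all GeneIDs annotated
  to the KO (the expected number of sequences of that gene);
* **richness** — number of distinct GeneIDs (distinct sequences);
* **variance** — sample variance (``ddof=1``) of the Estimated Copy values,
  undefined (NaN) when fewer than two GeneIDs were observed.

A protein complex encoded by a multi-gene operon is called *present* in a
sample only when every KO of the operon was detected there (richness >= 1
for each subunit); finding a single subunit gene without the others counts
as absent. Detection reflects genetic potential only, not expression.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import numpy as np
import pandas as pd

from .catalog import GeneCatalog

METRIC_COLUMNS = ("abundance", "richness", "variance")


def compute_metrics(records: pd.DataFrame, catalog: GeneCatalog) -> pd.DataFrame:
    """Compute abundance/richness/variance for every (sample, catalog KO).

    Parameters
    ----------
    records:
        Validated long table with columns ``sample_id, gene_id, ko,
        estimated_copy`` (e.g. from :func:`ncycle.catalog.read_all_gene_records`).
    catalog:
        Defines the KO axis; KOs with no records in a sample get explicit
        zero rows (abundance 0, richness 0, variance NaN).

    Returns
    -------
    Long DataFrame with columns ``sample_id, ko, abundance, richness,
    variance``, one row per (sample, catalog KO). Total abundance equals the
    total estimated copy of the input records exactly.
    """
    samples = sorted(records["sample_id"].unique())
    unknown = set(records["ko"]) - set(catalog.kos)
    if unknown:
        raise ValueError(f"records contain non-catalog KOs: {sorted(unknown)}")
    grouped = records.groupby(["sample_id", "ko"])["estimated_copy"].agg(
        abundance="sum", richness="count", variance=lambda v: v.var(ddof=1)
    )
    full_index = pd.MultiIndex.from_product(
        [samples, list(catalog.kos)], names=["sample_id", "ko"]
    )
    out = grouped.reindex(full_index)
    out["abundance"] = out["abundance"].fillna(0.0)
    out["richness"] = out["richness"].fillna(0).astype(int)
    return out.reset_index()


def metric_matrix(metrics: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Pivot long metrics to a samples x KO matrix of one statistic."""
    if metric not in METRIC_COLUMNS:
        raise ValueError(f"metric must be one of {METRIC_COLUMNS}, got {metric!r}")
    return metrics.pivot(index="sample_id", columns="ko", values=metric)


def call_protein_presence(
    metrics: pd.DataFrame, catalog: GeneCatalog
) -> pd.DataFrame:
    """Operon-completeness presence calls.

    ``present`` is the conjunction of richness >= 1 over every KO of the
    protein's operon; a partial operon (some but not all subunits detected)
    is absent.

    Returns a DataFrame ``sample_id, protein, present`` (bool), one row per
    (sample, catalog protein).
    """
    rich = metric_matrix(metrics, "richness")
    rows = []
    for protein in catalog.proteins:
        kos = sorted(catalog.members_of_protein(protein))
        detected = (rich[kos] >= 1).all(axis=1)
        for sample_id, present in detected.items():
            rows.append((sample_id, protein, bool(present)))
    return pd.DataFrame(rows, columns=["sample_id", "protein", "present"])


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (printed-report style: 21.875 -> 21.9)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def prevalence(table: pd.DataFrame, item: str) -> float:
    """Percentage of samples in which *item* was detected, to one decimal.

    ``table`` is either a presence table (columns ``sample_id, protein,
    present``; *item* names a protein) or a metrics table (columns include
    ``ko`` and ``richness``; *item* names a KO, detected iff richness >= 1).
    The denominator is the full sample set of the table.
    """
    if "protein" in table.columns:
        sub = table[table["protein"] == item]
        if sub.empty:
            raise KeyError(f"protein {item!r} not present in table")
        flags = sub.set_index("sample_id")["present"]
    elif "ko" in table.columns:
        sub = table[table["ko"] == item]
        if sub.empty:
            raise KeyError(f"KO {item!r} not present in table")
        flags = sub.set_index("sample_id")["richness"] >= 1
    else:
        raise ValueError("table must be a presence or metrics table")
    return prevalence_from_flags(flags.tolist())


def prevalence_from_flags(flags: Iterable[bool]) -> float:
    """100 * (#detected)/n, rounded half-away-from-zero to one decimal."""
    flags = list(flags)
    n = len(flags)
    if n == 0:
        raise ValueError("prevalence undefined for an empty sample set")
    return round_half_up(100.0 * sum(bool(f) for f in flags) / n, 1)


def write_metrics(
    metrics: pd.DataFrame, catalog: GeneCatalog, path
) -> None:
    """Export long-format metrics TSV with gene-symbol aliases.

    Columns: ``sample_id, ko, gene_symbols, abundance, richness, variance``;
    an undefined variance is written as an empty field.
    """
    out = metrics.copy()
    out.insert(2, "gene_symbols", out["ko"].map(catalog.gene_label))
    out.to_csv(path, sep="\t", index=False, na_rep="")


def write_presence(presence: pd.DataFrame, path) -> None:
    """Export presence TSV ``sample_id, protein, present`` with 0/1 flags."""
    out = presence.copy()
    out["present"] = out["present"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def brute_force_metrics(
    records: pd.DataFrame, catalog: GeneCatalog
) -> pd.DataFrame:
    """Record-by-record reference recomputation of :func:`compute_metrics`.

    Pure-Python accumulation (Welford-free, two-pass variance) kept as an
    independent oracle for property tests; do not use on large tables.
    """
    copies: dict[tuple[str, str], list[float]] = {}
    for row in records.itertuples(index=False):
        copies.setdefault((row.sample_id, row.ko), []).append(row.estimated_copy)
    rows = []
    for sample_id in sorted(records["sample_id"].unique()):
        for ko in catalog.kos:
            vals = copies.get((sample_id, ko), [])
            n = len(vals)
            abundance = math.fsum(vals)
            if n >= 2:
                mean = abundance / n
                variance = math.fsum((v - mean) ** 2 for v in vals) / (n - 1)
            else:
                variance = np.nan
            rows.append((sample_id, ko, abundance, n, variance))
    return pd.DataFrame(
        rows, columns=["sample_id", "ko", "abundance", "richness", "variance"]
    )
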