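"""Discretization, transaction encoding and Apriori association-rule mining.

Quantitative covariates are discretized into empirical-quantile categories —
two bins split at the median (``<50%`` / ``>50%``) or three bins split at the
30th and 70th percentiles (``<30%`` / ``30-70%`` / ``>70%``). Each sample then
becomes a *transaction*: the set of its covariate category items plus one
``Protein=Present`` or ``Protein=Absent`` item per catalog protein. Frequent
item-sets are mined with a level-wise Apriori (downward-closure pruning) and
turned into association rules ``antecedent => consequent`` scored by

* support    — P(antecedent and consequent) over all transactions,
* confidence — P(consequent | antecedent),
* lift       — confidence / P(consequent); 1 means independence.

Items are plain ``"variable=category"`` strings; item-sets are frozensets.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ncycle")

TWO_BIN_LABELS = ("<50%", ">50%")
THREE_BIN_LABELS = ("<30%", "30-70%", ">70%")


@dataclass(frozen=True)
class Discretization:
    """Categories per sample plus the quantile cut points that produced them."""

    categories: pd.Series  # str or NaN per sample
    cut_points: tuple[float, ...]
    degenerate: bool = False


def discretize(values: pd.Series, scheme: int = 3) -> Discretization:
    """Quantile-discretize one covariate.

    Parameters
    ----------
    values:
        Numeric series indexed by sample_id; NaN entries emit no category.
    scheme:
        2 — split at the empirical median into ``<50%`` / ``>50%``;
        3 — split at the 30th/70th percentiles into ``<30%`` / ``30-70%`` /
        ``>70%``. Quantiles use linear interpolation between order
        statistics; a value tied with the lower cut goes to the lower bin,
        one at or above the upper cut to the upper bin.

    Notes
    -----
    A constant vector yields a single category and is flagged degenerate so
    that callers can exclude it from mining.
    """
    if scheme not in (2, 3):
        raise ValueError(f"scheme must be 2 or 3, got {scheme}")
    vals = pd.to_numeric(values, errors="coerce")
    finite = vals.dropna()
    if finite.empty:
        raise ValueError("discretize needs at least one non-missing value")
    if finite.nunique() == 1:
        cats = vals.map(lambda v: TWO_BIN_LABELS[0] if np.isfinite(v) else np.nan)
        return Discretization(cats, (float(finite.iloc[0]),), degenerate=True)
    if scheme == 2:
        (cut,) = np.percentile(finite, [50.0])
        def label(v: float) -> str:
            return TWO_BIN_LABELS[0] if v <= cut else TWO_BIN_LABELS[1]
        cuts = (float(cut),)
    else:
        lo, hi = np.percentile(finite, [30.0, 70.0])
        def label(v: float) -> str:
            if v >= hi:
                return THREE_BIN_LABELS[2]
            if v <= lo:
                return THREE_BIN_LABELS[0]
            return THREE_BIN_LABELS[1]
        cuts = (float(lo), float(hi))
    cats = vals.map(lambda v: label(v) if np.isfinite(v) else np.nan)
    return Discretization(cats, cuts)


def discretize_table(
    env: pd.DataFrame,
    schemes: Mapping[str, int] | int = 3,
    exclude: Sequence[str] = ("x", "y"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Discretize every covariate column of a metadata table.

    ``schemes`` is either a single scheme applied to all columns or a
    per-variable mapping (variables absent from the mapping default to 3
    bins). Returns ``(categories, partition)`` where ``partition`` records
    per-variable cut points and the degenerate flag — the discretization
    report that accompanies mined rules. Degenerate variables are dropped
    from the categories table (single-category items carry no information).
    """
    cat_cols: dict[str, pd.Series] = {}
    part_rows = []
    for col in env.columns:
        if col in exclude:
            continue
        scheme = schemes if isinstance(schemes, int) else schemes.get(col, 3)
        disc = discretize(env[col], scheme)
        part_rows.append(
            (col, scheme, ";".join(repr(c) for c in disc.cut_points), disc.degenerate)
        )
        if disc.degenerate:
            logger.info("variable %s is constant; excluded from mining", col)
            continue
        cat_cols[col] = disc.categories
    categories = pd.DataFrame(cat_cols, index=env.index)
    partition = pd.DataFrame(
        part_rows, columns=["variable", "scheme", "cut_points", "degenerate"]
    )
    return categories, partition


# ---------------------------------------------------------------------------
# Transactions
# ---------------------------------------------------------------------------


def item(variable: str, category: str) -> str:
    return f"{variable}={category}"


@dataclass
class TransactionDB:
    """Item-encoded samples: one frozenset of ``"var=cat"`` items per sample."""

    transactions: list[frozenset[str]]
    sample_ids: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.transactions)

    @property
    def alphabet(self) -> frozenset[str]:
        out: set[str] = set()
        for t in self.transactions:
            out |= t
        return frozenset(out)

    def support_count(self, itemset: frozenset[str]) -> int:
        return sum(1 for t in self.transactions if itemset <= t)

    def support(self, itemset: frozenset[str]) -> float:
        return self.support_count(itemset) / self.n


def build_transactions(
    categories: pd.DataFrame,
    presence: pd.DataFrame | None = None,
    absence_items: bool = True,
) -> TransactionDB:
    """Encode samples as transactions of covariate categories + presence calls.

    Parameters
    ----------
    categories:
        Sample-indexed table of category labels (NaN = no item for that
        variable in that transaction).
    presence:
        Optional ``sample_id, protein, present`` table; each sample gains a
        ``Protein=Present`` item and, when ``absence_items`` is true, a
        ``Protein=Absent`` item for undetected operons. With
        ``absence_items=False`` absence is encoded by the mere lack of the
        presence item.
    """
    samples = list(categories.index)
    tx: dict[str, set[str]] = {s: set() for s in samples}
    for col in categories.columns:
        for s, cat in categories[col].items():
            if isinstance(cat, str):
                tx[s].add(item(col, cat))
    if presence is not None:
        for row in presence.itertuples(index=False):
            if row.sample_id not in tx:
                continue
            if row.present:
                tx[row.sample_id].add(item(row.protein, "Present"))
            elif absence_items:
                tx[row.sample_id].add(item(row.protein, "Absent"))
    return TransactionDB([frozenset(tx[s]) for s in samples], samples)


def write_baskets(db: TransactionDB, path) -> None:
    """Basket export: one line per sample, comma-separated sorted items."""
    with open(path, "w") as fh:
        for sid, t in zip(db.sample_ids, db.transactions):
            fh.write(sid + "\t" + ",".join(sorted(t)) + "\n")


# ---------------------------------------------------------------------------
# Apriori
# ---------------------------------------------------------------------------


def apriori(
    db: TransactionDB,
    min_support: float,
    max_len: int | None = None,
) -> dict[frozenset[str], float]:
    """Frequent item-sets by level-wise Apriori with downward-closure pruning.

    Returns every item-set of size 1..max_len whose support >= min_support,
    mapped to its support. ``max_len=None`` mines the full lattice.
    """
    if not 0 < min_support <= 1:
        raise ValueError(f"min_support must be in (0, 1], got {min_support}")
    if db.n < 1:
        raise ValueError("transaction database is empty")
    min_count = min_support * db.n
    # L1
    counts: dict[frozenset[str], int] = {}
    for t in db.transactions:
        for it in t:
            key = frozenset((it,))
            counts[key] = counts.get(key, 0) + 1
    frequent: dict[frozenset[str], float] = {
        s: c / db.n for s, c in counts.items() if c >= min_count
    }
    level = [s for s in frequent]
    k = 1
    while level and (max_len is None or k < max_len):
        k += 1
        candidates = _candidates(level, k)
        if not candidates:
            break
        counts = {c: 0 for c in candidates}
        for t in db.transactions:
            for c in candidates:
                if c <= t:
                    counts[c] += 1
        level = []
        for c, cnt in counts.items():
            if cnt >= min_count:
                frequent[c] = cnt / db.n
                level.append(c)
    return frequent


def _candidates(level: list[frozenset[str]], k: int) -> list[frozenset[str]]:
    """Join frequent (k-1)-sets sharing a (k-2)-prefix; prune by closure."""
    prev = set(level)
    sorted_level = [tuple(sorted(s)) for s in level]
    sorted_level.sort()
    out = []
    for i, a in enumerate(sorted_level):
        for b in sorted_level[i + 1 :]:
            if a[: k - 2] != b[: k - 2]:
                break
            cand = frozenset(a) | frozenset(b)
            if len(cand) != k:
                continue
            if all(cand - {it} in prev for it in cand):
                out.append(cand)
    return out


# ---------------------------------------------------------------------------
# Rule generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset[str]
    consequent: frozenset[str]
    support: float
    confidence: float
    lift: float
    n_antecedent: int
    n_both: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lhs = ", ".join(sorted(self.antecedent))
        rhs = ", ".join(sorted(self.consequent))
        return (
            f"{{{lhs}}} => {{{rhs}}} "
            f"(supp={self.support:.3f}, conf={self.confidence:.3f}, "
            f"lift={self.lift:.2f})"
        )


def generate_rules(
    frequent: Mapping[frozenset[str], float],
    db: TransactionDB,
    min_confidence: float,
    consequent_filter: Callable[[frozenset[str]], bool] | None = None,
    max_antecedent_len: int | None = None,
) -> list[AssociationRule]:
    """Emit all rules from frequent item-sets meeting ``min_confidence``.

    Every antecedent/consequent bipartition of each frequent set of size >= 2
    is considered; ``consequent_filter`` restricts admissible consequents
    (e.g. :func:`single_protein_consequent` reproduces the operon-rule
    screen). Support, confidence and lift are exact ratios of transaction
    counts. A consequent with zero support would make lift undefined; such
    rules are dropped with a log notice (cannot arise from frequent sets).
    """
    rules: list[AssociationRule] = []
    n = db.n
    for itemset, supp in frequent.items():
        if len(itemset) < 2:
            continue
        n_both = round(supp * n)
        for r in range(1, len(itemset)):
            for consequent_tuple in itertools.combinations(sorted(itemset), r):
                consequent = frozenset(consequent_tuple)
                if consequent_filter is not None and not consequent_filter(consequent):
                    continue
                antecedent = itemset - consequent
                if max_antecedent_len is not None and len(antecedent) > max_antecedent_len:
                    continue
                supp_ant = frequent.get(antecedent)
                if supp_ant is None:
                    supp_ant = db.support(antecedent)
                supp_con = frequent.get(consequent)
                if supp_con is None:
                    supp_con = db.support(consequent)
                if supp_con == 0:
                    logger.info("dropping rule with zero-support consequent: %s",
                                sorted(consequent))
                    continue
                confidence = supp / supp_ant
                if confidence < min_confidence:
                    continue
                rules.append(
                    AssociationRule(
                        antecedent=antecedent,
                        consequent=consequent,
                        support=supp,
                        confidence=confidence,
                        lift=confidence / supp_con,
                        n_antecedent=round(supp_ant * n),
                        n_both=n_both,
                    )
                )
    rules.sort(key=lambda r: (-r.lift, -r.support, sorted(r.antecedent)))
    return rules


def single_protein_consequent(proteins: Iterable[str]) -> Callable[[frozenset[str]], bool]:
    """Filter: consequent is exactly one ``Protein=Present/Absent`` item."""
    allowed = {
        item(p, cat) for p in proteins for cat in ("Present", "Absent")
    }
    def check(consequent: frozenset[str]) -> bool:
        return len(consequent) == 1 and next(iter(consequent)) in allowed
    return check


def mine_rules(
    db: TransactionDB,
    min_support: float = 0.1,
    min_confidence: float = 0.8,
    consequent_filter: Callable[[frozenset[str]], bool] | None = None,
    max_antecedent_len: int = 10,
) -> list[AssociationRule]:
    """Apriori + rule generation with the package defaults.

    The antecedent length cap (default 10 items) bounds the candidate
    lattice; it is logged because it truncates very long rules.
    """
    logger.info(
        "mining rules: min_support=%g min_confidence=%g max_antecedent_len=%d",
        min_support, min_confidence, max_antecedent_len,
    )
    frequent = apriori(db, min_support, max_len=max_antecedent_len + 1)
    return generate_rules(
        frequent, db, min_confidence,
        consequent_filter=consequent_filter,
        max_antecedent_len=max_antecedent_len,
    )


def group_rules_by_consequent(rules: Sequence[AssociationRule]) -> pd.DataFrame:
    """Rule matrix: rows = single-item consequents, columns = antecedents.

    Cells hold ``(support, lift)`` tuples (NaN where a consequent/antecedent
    combination was not mined) — the tabular form of a clustered rule plot.
    """
    for r in rules:
        if len(r.consequent) != 1:
            raise ValueError("group_rules_by_consequent needs single-item consequents")
    rows = sorted({next(iter(r.consequent)) for r in rules})
    cols: list[str] = []
    seen: set[str] = set()
    data: dict[tuple[str, str], tuple[float, float]] = {}
    for r in rules:
        con = next(iter(r.consequent))
        ant = ", ".join(sorted(r.antecedent))
        if ant not in seen:
            seen.add(ant)
            cols.append(ant)
        data[(con, ant)] = (r.support, r.lift)
    mat = pd.DataFrame(index=rows, columns=cols, dtype=object)
    for (con, ant), cell in data.items():
        mat.loc[con, ant] = cell
    mat.index.name = "consequent"
    return mat


def write_rules(rules: Sequence[AssociationRule], path) -> None:
    """Rule export TSV: token-list antecedent/consequent plus all statistics."""
    df = pd.DataFrame(
        {
            "antecedent": [",".join(sorted(r.antecedent)) for r in rules],
            "consequent": [",".join(sorted(r.consequent)) for r in rules],
            "support": [r.support for r in rules],
            "confidence": [r.confidence for r in rules],
            "lift": [r.lift for r in rules],
            "n_antecedent": [r.n_antecedent for r in rules],
            "n_both": [r.n_both for r in rules],
        }
    )
    df.to_csv(path, sep="\t", index=False)
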