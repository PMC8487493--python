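"""Candidate synaptic-transmission gene identification and calibration.

Candidate genes are found by case-insensitive keyword search over
free-text annotations, refined by optional include/exclude patterns
(broad terms such as "kinesin" or "dynein" are restricted to exclude
irrelevant matches).  The shipped default rule file covers the 39
synaptic-transmission protein families in five categories (ionotropic
receptors; synaptic vesicle proteins; vesicle-associated proteins;
synaptic plasma membrane proteins; reversibly membrane-associated
proteins) and is replaceable input, not ground truth.

:func:`random_set_calibration` asks whether an observed number of DE
candidates exceeds what same-sized random gene sets achieve.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import re

import numpy as np
import pandas as pd

__all__ = [
    "KeywordRule",
    "CandidateSet",
    "default_rules",
    "read_rules",
    "match_candidates",
    "random_set_calibration",
]


@dataclasses.dataclass(frozen=True)
class KeywordRule:
    """One keyword with category (1-5), family label and refinements.

    ``include_patterns``: if nonempty, at least one must match the
    annotation string (case-insensitive regex).  ``exclude_patterns``:
    none may match.
    """

    keyword: str
    category: int
    family_name: str
    include_patterns: tuple[str, ...] = ()
    exclude_patterns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.keyword:
            raise ValueError("keyword must be nonempty")
        if self.category not in {1, 2, 3, 4, 5}:
            raise ValueError("category must be in 1..5")

    def matches(self, text: str) -> bool:
        low = text.lower()
        if self.keyword.lower() not in low:
            return False
        try:
            if self.include_patterns and not any(
                    re.search(p, low, re.IGNORECASE) for p in self.include_patterns):
                return False
            if any(re.search(p, low, re.IGNORECASE) for p in self.exclude_patterns):
                return False
        except re.error as exc:
            raise ValueError(
                f"malformed pattern in rule for {self.family_name!r}: {exc}") from exc
        return True


def _split(field) -> tuple[str, ...]:
    if field is None or (isinstance(field, float) and np.isnan(field)):
        return ()
    s = str(field).strip()
    return tuple(p for p in s.split(";") if p) if s else ()


def read_rules(path_or_buf) -> list[KeywordRule]:
    """Load rules from a TSV with columns keyword/category/family/include/exclude."""
    df = pd.read_csv(path_or_buf, sep="\t")
    rules = []
    for _, row in df.iterrows():
        rules.append(KeywordRule(
            keyword=str(row["keyword"]),
            category=int(row["category"]),
            family_name=str(row["family"]),
            include_patterns=_split(row.get("include")),
            exclude_patterns=_split(row.get("exclude")),
        ))
    return rules


def default_rules() -> list[KeywordRule]:
    """The packaged default rule set (39 families, 5 categories)."""
    ref = importlib.resources.files("neurodiverge") / "data" / "keywords.tsv"
    with ref.open("r") as fh:
        return read_rules(fh)


@dataclasses.dataclass
class CandidateSet:
    """Genes matched by the keyword rules, with category assignment.

    ``table`` is indexed by gene id with columns family, category,
    keyword (the first matching rule in rule order) and all_matches
    (semicolon-joined families of every matching rule).
    """

    table: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def category_counts(self) -> pd.Series:
        """Genes per primary category (a gene counts once per category)."""
        return self.table["category"].value_counts().sort_index()


def match_candidates(annotations: pd.DataFrame, rules: list[KeywordRule] | None = None,
                     expressed_gene_ids=None) -> CandidateSet:
    """Match annotation text against the keyword rules.

    ``annotations`` is indexed by gene id with an ``annotation`` column
    of pipe-separated free-text terms.  A gene matches a rule if any of
    its terms contains the keyword and survives the rule's include and
    exclude patterns.  The result is intersected with
    ``expressed_gene_ids`` when given (the post-filter expressed set).
    """
    if rules is None:
        rules = default_rules()
    if not rules:
        raise ValueError("rules must be nonempty")
    genes = annotations.index
    if expressed_gene_ids is not None:
        keep = set(expressed_gene_ids)
        genes = [g for g in genes if g in keep]
    rows = []
    for gene in genes:
        terms = str(annotations.loc[gene, "annotation"]).split("|")
        hits = [r for r in rules if any(r.matches(t) for t in terms)]
        if hits:
            first = hits[0]
            rows.append((gene, first.family_name, first.category, first.keyword,
                         ";".join(r.family_name for r in hits)))
    table = pd.DataFrame(rows, columns=["gene_id", "family", "category",
                                        "keyword", "all_matches"]).set_index("gene_id")
    return CandidateSet(table)


def random_set_calibration(significant, set_size: int, n_observed_sig: int,
                           n_reps: int = 10000, seed: int = 0):
    """Compare an observed DE count against random same-sized gene sets.

    ``significant`` is a boolean per-gene vector (or a DEResult, whose
    significance flags are used) over the whole tested gene universe.
    Draws ``n_reps`` uniform subsets of ``set_size`` genes without
    replacement; returns (mean_sig, p) where p is the proportion of
    draws with strictly more significant genes than ``n_observed_sig``.
    """
    if hasattr(significant, "table"):
        significant = significant.table["significant"]
    sig = np.asarray(significant, dtype=bool)
    total = sig.size
    if set_size <= 0:
        raise ValueError("set_size must be positive")
    if set_size > total:
        raise ValueError("set_size exceeds number of genes")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.empty(n_reps, dtype=np.int64)
    for i in range(n_reps):
        counts[i] = sig[rng.choice(total, size=set_size, replace=False)].sum()
    return float(counts.mean()), float((counts > n_observed_sig).mean())
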