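"""Genotype-phenotype association and family segregation concordance.

Carrier tumors (or patients) of one gene are compared against the tumors
of carriers of other genes for a binary pathology feature with the exact
Fisher engine; onset ages are compared with a Mann-Whitney U test whose
small-sample branch enumerates the exact permutation distribution (ties
included).  A case carrying pathogenic variants in two genes contributes
its tumors to both genes' carrier groups; such cases are flagged in the
result note.
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .data_model import ContingencyTable, FisherResult
from .enrichment import fisher_exact_2x2

__all__ = [
    "FEATURE_PREDICATES",
    "test_gene_phenotype",
    "mann_whitney_age",
    "segregation_concordance",
]

FEATURE_PREDICATES = {
    "histology_solid_tubular": ("histology", lambda v: v == "Solid Tubular"),
    "grade3": ("nuclear_grade", lambda v: int(v) == 3),
    "triple_negative": ("hormonal_subtype", lambda v: v == "Triple Negative"),
}

#: exact permutation enumeration up to this combined sample size
EXACT_N_MAX = 12


def test_gene_phenotype(
    tumor_table: pd.DataFrame,
    gene: str,
    feature: str,
    unit: str = "tumor",
) -> FisherResult:
    """Fisher test of a tumor feature between carriers of ``gene`` and the
    other carriers.

    ``tumor_table`` follows the tumors fixture schema (``case_id``,
    ``gene``, ``tumor_id``, ``histology``, ``hormonal_subtype``,
    ``nuclear_grade``).  Records with a missing feature value are
    excluded; ``unit`` is ``tumor`` (default, one row per distinct tumor)
    or ``patient``.
    """
    if feature not in FEATURE_PREDICATES:
        raise KeyError(f"unknown feature {feature!r}; options: {sorted(FEATURE_PREDICATES)}")
    column, predicate = FEATURE_PREDICATES[feature]

    df = tumor_table.copy()
    carrier_cases = set(df.loc[df["gene"] == gene, "case_id"])
    multi = (
        df.groupby("case_id")["gene"].nunique().loc[lambda s: s > 1].index.intersection(
            sorted(carrier_cases)
        )
    )

    df = df.dropna(subset=[column])
    df = df[df[column] != ""]
    if unit == "tumor":
        df = df.drop_duplicates(subset=["case_id", "tumor_id"])
        units = df
    elif unit == "patient":
        units = df.drop_duplicates(subset=["case_id"])
    else:
        raise ValueError(f"unknown unit {unit!r}")
    if units.empty:
        raise ValueError("no informative records for this feature")

    is_carrier = units["case_id"].isin(carrier_cases).to_numpy()
    has_feature = units[column].map(predicate).to_numpy(dtype=bool)
    a = int((is_carrier & has_feature).sum())
    b = int((is_carrier & ~has_feature).sum())
    c = int((~is_carrier & has_feature).sum())
    d = int((~is_carrier & ~has_feature).sum())
    if (a + c == 0) or (b + d == 0):
        raise ValueError(f"degenerate margin: feature {feature!r} constant across records")
    result = fisher_exact_2x2(ContingencyTable(a, b, c, d))
    if len(multi):
        result.method_note += (
            f"; multi-gene carrier case(s) {sorted(multi)} contribute to both carrier groups"
        )
    return result


def mann_whitney_age(
    ages_group: Sequence[float], ages_rest: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U with a two-sided p-value.

    Returns ``(U, p)`` where U counts pairs in which a group observation
    exceeds a rest observation (ties count 0.5).  With combined n at most
    12 the p-value is exact, from full enumeration of the permutation
    distribution of U (valid under ties); larger samples use the normal
    approximation with tie correction.
    """
    x = np.asarray(ages_group, dtype=float)
    y = np.asarray(ages_rest, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    u_obs = _u_statistic(x, y)
    if n1 + n2 <= EXACT_N_MAX:
        pooled = np.concatenate([x, y])
        center = n1 * n2 / 2.0
        dev_obs = abs(u_obs - center)
        count = 0
        total = 0
        idx = range(n1 + n2)
        for pick in combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(pick)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - center) >= dev_obs - 1e-9:
                count += 1
        return u_obs, count / total
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    ranks = rankdata(np.concatenate([x, y]))
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def segregation_concordance(
    family_genotypes: Mapping[str, str],
    phenotypes: Mapping[str, str],
) -> str:
    """Concordance of a family's variant with disease occurrence.

    ``concordant`` iff every genotyped member is either an affected
    carrier or an unaffected non-carrier.  Members with a genotype but no
    phenotype are excluded with a warning; fewer than two informative
    members is an error.
    """
    informative = []
    for member, genotype in family_genotypes.items():
        if genotype not in ("carrier", "non-carrier"):
            raise ValueError(f"bad genotype {genotype!r} for {member}")
        if member not in phenotypes:
            warnings.warn(f"member {member!r} has genotype but no phenotype; excluded",
                          stacklevel=2)
            continue
        informative.append(member)
    if len(informative) < 2:
        raise ValueError("segregation requires at least two genotyped, phenotyped members")
    for member in informative:
        carrier = family_genotypes[member] == "carrier"
        affected = phenotypes[member] == "affected_breast_or_ovary"
        if carrier != affected:
            return "discordant"
    return "concordant"
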