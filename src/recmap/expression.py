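"""Digital-expression statistics for a two-library design.

Expression is summarized as RPKM (reads per kilobase of transcript per
million mapped reads), ``1e9 * C / (N * L)`` for ``C`` reads uniquely
aligned to a gene of length ``L`` bp out of ``N`` uniquely aligned
library reads.  Equal expression between the two libraries is tested
with the Audic-Claverie exact test: conditional on the wild-type count
``x``, the mutant count under equal expression follows

    p(y | x) = (N2/N1)^y * (x+y)! / (x! y! (1 + N2/N1)^(x+y+1)),

a negative-binomial law in ``y`` with ``x+1`` successes and success
probability ``N1/(N1+N2)``.  All probabilities are computed in log
space; the default two-sided p doubles the smaller tail.  Multiple
testing is controlled with Benjamini-Hochberg step-up FDR, and a gene
is called differentially expressed when FDR <= 0.001 and
|log2(RPKM_wt / RPKM_mut)| >= 1 (boundary values pass).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests


@dataclass
class CountTable:
    """Gene counts for the wild-type (x) and mutant (y) libraries."""

    table: pd.DataFrame  # gene_id, length_bp, x, y
    samples: tuple[str, str] = ("wildtype", "mutant")

    def __post_init__(self) -> None:
        required = {"gene_id", "length_bp", "x", "y"}
        if required - set(self.table.columns):
            raise ValueError("count table needs columns gene_id, length_bp, x, y")
        if (self.table["length_bp"] < 1).any():
            raise ValueError("gene length must be >= 1")
        if (self.table[["x", "y"]] < 0).to_numpy().any():
            raise ValueError("negative counts")
        if self.table["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids")

    @property
    def n1(self) -> int:
        return int(self.table["x"].sum())

    @property
    def n2(self) -> int:
        return int(self.table["y"].sum())


def rpkm(c, n, length):
    """RPKM = 1e9 * C / (N * L)."""
    c = np.asarray(c, dtype=float)
    n = np.asarray(n, dtype=float)
    length = np.asarray(length, dtype=float)
    if np.any(n < 1) or np.any(length < 1):
        raise ValueError("N and L must be >= 1")
    return 1e9 * c / (n * length)


def ac_pointwise_log_p(x, y, n1, n2):
    """log p(y | x) of the Audic-Claverie conditional law."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if n1 < 1 or n2 < 1:
        raise ValueError("library sizes must be >= 1")
    log_r = np.log(n2) - np.log(n1)
    return (
        y * log_r
        + special.gammaln(x + y + 1)
        - special.gammaln(x + 1)
        - special.gammaln(y + 1)
        - (x + y + 1) * np.log1p(np.exp(log_r))
    )


def ac_equal_expression_test(x, y, n1, n2, two_sided: str = "doubled_tail"):
    """Audic-Claverie exact test of equal expression.

    Returns ``(pointwise_p, two_sided_p)``; both broadcast over array
    inputs.  Tails are evaluated through the negative-binomial identity
    ``y | x ~ NB(x + 1, N1/(N1+N2))`` and the two-sided p doubles the
    smaller of the two tails (``two_sided="minlike"`` instead sums all
    outcomes no more probable than the observed one).
    """
    if two_sided not in ("doubled_tail", "minlike"):
        raise ValueError(f"two_sided={two_sided!r} unknown")
    x_arr = np.atleast_1d(np.asarray(x, dtype=int))
    y_arr = np.atleast_1d(np.asarray(y, dtype=int))
    if np.any(x_arr < 0) or np.any(y_arr < 0):
        raise ValueError("counts must be >= 0")
    pointwise = np.exp(ac_pointwise_log_p(x_arr, y_arr, n1, n2))
    p_success = n1 / (n1 + n2)  # NB success prob: P(y) = C(x+y,y) p^(x+1) (1-p)^y
    lower = stats.nbinom.cdf(y_arr, x_arr + 1, p_success)
    upper = stats.nbinom.sf(y_arr - 1, x_arr + 1, p_success)
    if two_sided == "doubled_tail":
        p2 = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    else:
        p2 = np.empty(len(x_arr))
        for i, (xi, yi) in enumerate(zip(x_arr, y_arr)):
            log_obs = ac_pointwise_log_p(xi, yi, n1, n2)
            # sum over all y' with p(y') <= p(y_obs); the law is unimodal,
            # so scan out from the mode until the tail mass is negligible
            hi = int(max(yi, (xi + 1) * (n2 / n1))) + 200
            ys = np.arange(0, hi + 1)
            lp = ac_pointwise_log_p(np.full_like(ys, xi), ys, n1, n2)
            mass = np.exp(lp[lp <= log_obs + 1e-12]).sum()
            mass += stats.nbinom.sf(hi, xi + 1, p_success)  # conservative remainder
            p2[i] = min(1.0, mass)
    if np.isscalar(x) and np.isscalar(y):
        return float(pointwise[0]), float(p2[0])
    return pointwise, p2


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


CALL_UP = "up_in_mutant"
CALL_DOWN = "down_in_mutant"
CALL_NS = "ns"


def call_degs(
    count_table: CountTable, fdr_max: float = 0.001, min_abs_log2: float = 1.0,
    two_sided: str = "doubled_tail",
) -> pd.DataFrame:
    """Call differentially expressed genes between the two libraries.

    Genes with zero counts in both libraries are excluded before
    testing; a zero in exactly one library passes the fold-change
    criterion automatically (its log2 ratio is infinite).  The log2
    ratio is wild-type over mutant; calls are labelled relative to the
    mutant library.
    """
    df = count_table.table
    if df.empty:
        raise ValueError("empty count table")
    n1, n2 = count_table.n1, count_table.n2
    df = df.loc[(df["x"] > 0) | (df["y"] > 0)].reset_index(drop=True)
    x = df["x"].to_numpy()
    y = df["y"].to_numpy()
    length = df["length_bp"].to_numpy()
    rpkm_wt = rpkm(x, n1, length)
    rpkm_mut = rpkm(y, n2, length)
    with np.errstate(divide="ignore"):
        log2_ratio = np.log2(rpkm_wt) - np.log2(rpkm_mut)
    _, p = ac_equal_expression_test(x, y, n1, n2, two_sided=two_sided)
    q = bh_fdr(p)
    fold_ok = np.abs(log2_ratio) >= min_abs_log2  # +/- inf pass automatically
    sig = (q <= fdr_max) & fold_ok
    call = np.where(~sig, CALL_NS, np.where(log2_ratio > 0, CALL_DOWN, CALL_UP))
    return pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "x": x,
            "y": y,
            "rpkm_wt": rpkm_wt,
            "rpkm_mut": rpkm_mut,
            "log2_ratio": log2_ratio,
            "p": p,
            "q": q,
            "call": call,
        }
    )


def merge_deg_lists(list_a, list_b) -> pd.DataFrame:
    """Union of two DEG identifier lists keyed on case-folded ids.

    Returns a table with the representative id and provenance
    (``a``, ``b`` or ``both``).
    """
    seen: dict[str, dict] = {}
    for gid in list_a:
        seen.setdefault(str(gid).casefold(), {"gene_id": str(gid), "provenance": "a"})
    for gid in list_b:
        key = str(gid).casefold()
        if key in seen:
            seen[key]["provenance"] = "both"
        else:
            seen[key] = {"gene_id": str(gid), "provenance": "b"}
    return pd.DataFrame(list(seen.values()))


def ddct_fold_change(
    qpcr: pd.DataFrame, reference_group: str = "wildtype", target_group: str = "mutant"
) -> pd.Series:
    """Relative expression by the 2^-ddCt method, per gene.

    ``qpcr`` is tidy with columns ``gene, group, ct_target, ct_ref``
    (one row per replicate).  dCt = mean(ct_target) - mean(ct_ref) per
    group; ddCt = dCt(target group) - dCt(reference group); the fold
    change ``2 ** -ddCt`` is relative to the reference group.
    """
    required = {"gene", "group", "ct_target", "ct_ref"}
    if required - set(qpcr.columns):
        raise ValueError("qpcr table needs columns gene, group, ct_target, ct_ref")
    if qpcr[["ct_target", "ct_ref"]].isna().to_numpy().any():
        raise ValueError("Ct values must be finite")
    folds = {}
    for gene, sub in qpcr.groupby("gene"):
        groups = set(sub["group"])
        if not {reference_group, target_group} <= groups:
            raise ValueError(f"gene {gene!r} lacks one of the groups")
        dct = {
            g: sub.loc[sub["group"] == g, "ct_target"].mean()
            - sub.loc[sub["group"] == g, "ct_ref"].mean()
            for g in (reference_group, target_group)
        }
        ddct = dct[target_group] - dct[reference_group]
        folds[gene] = 2.0 ** (-ddct)
    return pd.Series(folds, name="fold_change")


def overrepresentation_test(
    query_set, gene_sets, universe
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query in annotated sets.

    ``gene_sets`` maps set name -> genes (a single set may be passed as
    a bare iterable).  Returns a table with the overlap ratio ``k/K``,
    the upper-tail hypergeometric p, and BH q across the sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_set)
    if query - universe:
        raise ValueError("query set not contained in universe")
    if not isinstance(gene_sets, dict):
        gene_sets = {"set": set(gene_sets)}
    rows = []
    m_univ = len(universe)
    n_query = len(query)
    for name, genes in gene_sets.items():
        genes = set(genes)
        if genes - universe:
            raise ValueError(f"gene set {name!r} not contained in universe")
        k = len(query & genes)
        p = float(stats.hypergeom.sf(k - 1, m_univ, len(genes), n_query))
        rows.append({"set": name, "overlap": k, "ratio": f"{k}/{len(genes)}", "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out
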