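"""Enrichment of sex-linked DEGs among diet DEGs, with matched bootstrap null.

Genes are cross-classified by significance (adjusted p < 0.05) in a sex
contrast and a diet contrast; enrichment is the fraction of diet DEGs that
are also sex DEGs, tested by a two-tailed Fisher's exact test. The null is
calibrated with expression-matched control sets: for every diet DEG one
non-diet-DEG within a relative mean-expression window stands in, and the
contingency/Fisher construction is repeated over many such sets, reporting
the median enrichment and median p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DEGContingency",
    "EnrichmentResult",
    "deg_contingency",
    "fisher_enrichment",
    "matched_control_sets",
    "bootstrap_enrichment",
]

DEFAULT_ALPHA = 0.05
DEFAULT_EXPR_TOLERANCE = 0.02
DEFAULT_B = 1000

REQUIRED_COLS = ("gene_id", "padj", "mean_expr")


@dataclass
class DEGContingency:
    """2x2 cross-classification of a shared gene universe.

    g1: significant in both contrasts; g2: sex-only; g3: diet-only;
    g4: neither. Cells always sum to the filtered universe.
    """

    g1: int
    g2: int
    g3: int
    g4: int

    @property
    def universe(self) -> int:
        return self.g1 + self.g2 + self.g3 + self.g4

    def as_table(self) -> np.ndarray:
        return np.array([[self.g1, self.g2], [self.g3, self.g4]])


@dataclass
class EnrichmentResult:
    enrichment: float
    fisher_p: float
    boot_median_enrichment: float
    boot_median_p: float
    B: int
    seed: int
    tolerance: float
    boot_enrichments: np.ndarray | None = None
    boot_ps: np.ndarray | None = None


def _check_table(df: pd.DataFrame, name: str) -> pd.DataFrame:
    if df.index.name == "gene_id":
        required = set(REQUIRED_COLS) - {"gene_id"}
    else:
        required = set(REQUIRED_COLS)
    lacking = required - set(df.columns)
    if lacking:
        raise ValueError(f"{name} DE table lacks columns {sorted(lacking)}")
    return df if df.index.name == "gene_id" else df.set_index("gene_id")


def deg_contingency(
    sex_table: pd.DataFrame, diet_table: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> DEGContingency:
    """Cross-classify genes by sex/diet significance at ``padj < alpha``.

    Genes with a missing adjusted p in either table are removed first; the
    remaining shared gene ids form the universe.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0,1]")
    sex = _check_table(sex_table, "sex")
    diet = _check_table(diet_table, "diet")
    shared = sex.index.intersection(diet.index)
    ps = sex.loc[shared, "padj"]
    pd_ = diet.loc[shared, "padj"]
    keep = ps.notna() & pd_.notna()
    if keep.sum() == 0:
        raise ValueError("empty universe after removing genes with missing padj")
    s = (ps[keep] < alpha).to_numpy()
    d = (pd_[keep] < alpha).to_numpy()
    return DEGContingency(
        g1=int((s & d).sum()), g2=int((s & ~d).sum()),
        g3=int((~s & d).sum()), g4=int((~s & ~d).sum()),
    )


def fisher_enrichment(table: DEGContingency) -> tuple[float, float]:
    """(enrichment, two-tailed Fisher p) for a sex-by-diet contingency.

    Enrichment is g1 / (g1 + g3), the sex-DEG fraction of diet DEGs. The
    two-tailed p sums hypergeometric outcome probabilities no larger than
    the observed table's probability.
    """
    if table.universe == 0:
        raise ValueError("empty universe")
    n_diet = table.g1 + table.g3
    if n_diet == 0:
        raise ValueError("no diet DEGs; enrichment undefined")
    enrichment = table.g1 / n_diet
    p = float(sps.fisher_exact(table.as_table(), alternative="two-sided")[1])
    return float(enrichment), p


def matched_control_sets(
    diet_degs: pd.DataFrame,
    non_diet_degs: pd.DataFrame,
    tolerance: float = DEFAULT_EXPR_TOLERANCE,
) -> dict[str, np.ndarray]:
    """Expression-matched candidate pool per diet DEG.

    For diet DEG g, the pool holds every non-diet DEG whose mean expression
    is within ``tolerance`` (relative, default 2%) of g's mean expression.
    An empty pool is an error naming the gene — widen the tolerance.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    dd = _check_table(diet_degs, "diet DEG")
    nd = _check_table(non_diet_degs, "non-diet DEG")
    cand_expr = nd["mean_expr"].to_numpy(float)
    cand_ids = nd.index.to_numpy()
    order = np.argsort(cand_expr)
    cand_expr, cand_ids = cand_expr[order], cand_ids[order]
    pools: dict[str, np.ndarray] = {}
    for gene, expr in dd["mean_expr"].items():
        lo = np.searchsorted(cand_expr, expr * (1 - tolerance), side="left")
        hi = np.searchsorted(cand_expr, expr * (1 + tolerance), side="right")
        pool = cand_ids[lo:hi]
        if pool.size == 0:
            raise ValueError(
                f"no expression-matched control for gene {gene!r} at tolerance {tolerance}"
            )
        pools[str(gene)] = pool
    return pools


def _control_contingency(
    control_set: set, sex_significant: set, universe: set
) -> DEGContingency:
    g1 = len(control_set & sex_significant)
    g3 = len(control_set - sex_significant)
    g2 = len(sex_significant - control_set)
    g4 = len(universe) - g1 - g2 - g3
    return DEGContingency(g1=g1, g2=g2, g3=g3, g4=g4)


def bootstrap_enrichment(
    sex_table: pd.DataFrame,
    diet_table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    tolerance: float = DEFAULT_EXPR_TOLERANCE,
    B: int = DEFAULT_B,
    seed: int = 0,
    keep_distributions: bool = False,
) -> EnrichmentResult:
    """Observed enrichment plus the expression-matched bootstrap null.

    Each of B iterations draws one gene per matched pool (independent
    draws; a gene drawn for two pools is collapsed when the contingency is
    built) to form a control set the size of the diet-DEG list, and runs
    the same contingency/Fisher construction with control-set membership
    in place of diet-DEG status. Medians over iterations summarize the
    null. The control universe is every gene with a non-missing padj in
    the sex table.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    obs_table = deg_contingency(sex_table, diet_table, alpha=alpha)
    enrichment, fisher_p = fisher_enrichment(obs_table)

    sex = _check_table(sex_table, "sex")
    diet = _check_table(diet_table, "diet")
    sex = sex[sex["padj"].notna()]
    diet = diet[diet["padj"].notna()]
    shared = sex.index.intersection(diet.index)
    diet = diet.loc[shared]
    is_diet_deg = diet["padj"] < alpha
    pools = matched_control_sets(diet[is_diet_deg], diet[~is_diet_deg], tolerance)

    universe = set(map(str, sex.index))
    sex_sig = set(map(str, sex.index[sex["padj"] < alpha]))

    rng = np.random.default_rng(seed)
    pool_list = list(pools.values())
    enr = np.empty(B)
    ps = np.empty(B)
    for i in range(B):
        control = {str(rng.choice(p)) for p in pool_list}
        tab = _control_contingency(control, sex_sig, universe)
        if tab.g1 + tab.g3 == 0:
            enr[i], ps[i] = np.nan, np.nan
            continue
        enr[i], ps[i] = fisher_enrichment(tab)
    return EnrichmentResult(
        enrichment=enrichment,
        fisher_p=fisher_p,
        boot_median_enrichment=float(np.nanmedian(enr)),
        boot_median_p=float(np.nanmedian(ps)),
        B=B,
        seed=seed,
        tolerance=tolerance,
        boot_enrichments=enr if keep_distributions else None,
        boot_ps=ps if keep_distributions else None,
    )
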