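"""Merge genomic and proteomic per-pathway p-values into final p-values.

Pathways enriched in both layers are combined with Fisher's combined
probability test: X² = −2(ln p_g + ln p_p) ~ chi-square with df = 4, whose
upper tail has the closed form e^(−X²/2)·(1 + X²/2).  Pathways enriched in
only one layer pass their single-layer p through unchanged.  All arithmetic
is done on ln p so inputs down to 1e-300 combine without underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .enrichment import LayerPathwayResult
from .io_formats import PathwayCollection


@dataclass
class MergedPathwayResult:
    pathway_id: str
    name: str = ""
    p_genomic: float | None = None
    p_proteomic: float | None = None
    fisher_statistic: float | None = None   # X² when both layers present
    df: int | None = None
    p_final: float = 1.0
    genes: frozenset = frozenset()
    snps: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.p_genomic is None and self.p_proteomic is None:
            raise ValueError(f"{self.pathway_id}: no layer p-value present")
        if not (0.0 < self.p_final <= 1.0):
            raise ValueError(f"{self.pathway_id}: p_final outside (0, 1]")


def _chi2_upper_tail_log(x2: float, df: int) -> float:
    """Upper tail of chi-square(df even) at x2, evaluated in log space.

    For even df = 2m the survival function is
    e^(−x/2) · Σ_{j<m} (x/2)^j / j!; summed on the log scale so results
    remain accurate down to ~1e-300.
    """
    if df % 2 != 0 or df < 2:
        raise ValueError("closed form requires even df >= 2")
    if x2 <= 0:
        return 1.0
    h = x2 / 2.0
    # log-sum-exp of terms j*ln(h) - ln(j!)
    log_terms = []
    log_fact = 0.0
    for j in range(df // 2):
        if j > 0:
            log_fact += math.log(j)
        log_terms.append(j * math.log(h) - log_fact)
    m = max(log_terms)
    log_sum = m + math.log(sum(math.exp(t - m) for t in log_terms))
    log_p = -h + log_sum
    # two 1e-300 inputs give a true p around 1e-597; floor to the package-
    # wide representable minimum so results stay in (0, 1]
    return min(1.0, max(math.exp(log_p), 1e-300))


def fisher_merge(p_g: float, p_p: float) -> float:
    """Fisher's combined probability of two independent p-values (df = 4).

    Symmetric in its arguments; computed in log space, so p-values down to
    1e-300 are supported.
    """
    for p in (p_g, p_p):
        if not (0.0 < p <= 1.0) or math.isnan(p):
            raise ValueError(f"p-value outside (0, 1]: {p}")
    x2 = -2.0 * (math.log(p_g) + math.log(p_p))
    return _chi2_upper_tail_log(x2, df=4)


def fisher_merge_many(pvals: list[float]) -> float:
    """Fisher combination of m ≥ 1 p-values (df = 2m); generalised form."""
    if not pvals:
        raise ValueError("need >=1 p-value")
    for p in pvals:
        if not (0.0 < p <= 1.0) or math.isnan(p):
            raise ValueError(f"p-value outside (0, 1]: {p}")
    x2 = -2.0 * sum(math.log(p) for p in pvals)
    return _chi2_upper_tail_log(x2, df=2 * len(pvals))


def merge_layers(
    genomic: list[LayerPathwayResult],
    proteomic: list[LayerPathwayResult],
    pathways: PathwayCollection | None = None,
) -> list[MergedPathwayResult]:
    """Fisher-merge shared pathways; pass single-layer pathways through.

    Output is sorted by ascending final p-value, ties broken by pathway id.
    Pathway names are filled in from *pathways* when provided.
    """
    names = {}
    if pathways is not None:
        names = {r.pathway_id: r.name for r in pathways}
    g = {r.pathway_id: r for r in genomic}
    p = {r.pathway_id: r for r in proteomic}
    out: list[MergedPathwayResult] = []
    for pid in sorted(set(g) | set(p)):
        rg, rp = g.get(pid), p.get(pid)
        if rg is not None and rp is not None:
            x2 = -2.0 * (math.log(rg.p_value) + math.log(rp.p_value))
            out.append(MergedPathwayResult(
                pathway_id=pid, name=names.get(pid, ""),
                p_genomic=rg.p_value, p_proteomic=rp.p_value,
                fisher_statistic=x2, df=4,
                p_final=fisher_merge(rg.p_value, rp.p_value),
                genes=rg.genes | rp.genes, snps=rg.snps | rp.snps,
            ))
        else:
            r = rg if rg is not None else rp
            out.append(MergedPathwayResult(
                pathway_id=pid, name=names.get(pid, ""),
                p_genomic=r.p_value if rg is not None else None,
                p_proteomic=r.p_value if rp is not None else None,
                p_final=r.p_value, genes=r.genes, snps=r.snps,
            ))
    out.sort(key=lambda r: (r.p_final, r.pathway_id))
    return out
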