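"""SNP quality control and case/control genotypic association.

The QC stage mirrors a standard small-cohort GWAS pre-filter: samples are
kept only when their call rate is strictly above 98%; SNPs are then excluded
in a fixed order — Y chromosome first, then call rate < 95%, then minor
allele frequency < 0.01 — and finally thinned by linkage-disequilibrium
pruning (squared Pearson correlation of genotype codes > 0.5 within a
sliding window).  Association uses the genotypic (2 df) Pearson chi-square
test on the 2×3 case/control × genotype table.

Boundary semantics follow the wording the thresholds come from: the sample
filter keeps call rates strictly *greater than* the threshold, SNP filters
exclude strictly *lower than* theirs, and the significance filter keeps
p strictly *lower than* alpha.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass
class QcReport:
    """Record of one QC stage: per-item metrics and exclusions with reasons."""

    sample_call_rate: dict = field(default_factory=dict)
    snp_call_rate: dict = field(default_factory=dict)
    snp_maf: dict = field(default_factory=dict)
    excluded_snps: dict = field(default_factory=dict)     # snp_id -> reason
    excluded_samples: dict = field(default_factory=dict)  # sample_id -> reason
    n_snps_retained: int = 0

    VALID_SNP_REASONS = ("Y_CHROM", "CALL_RATE", "MAF", "LD_PRUNE")

    def merge(self, other: "QcReport") -> "QcReport":
        """Combine sequential stage reports; first-triggered reason wins."""
        out = QcReport(
            sample_call_rate={**self.sample_call_rate, **other.sample_call_rate},
            snp_call_rate={**self.snp_call_rate, **other.snp_call_rate},
            snp_maf={**self.snp_maf, **other.snp_maf},
            excluded_snps={**other.excluded_snps, **self.excluded_snps},
            excluded_samples={**other.excluded_samples, **self.excluded_samples},
            n_snps_retained=other.n_snps_retained,
        )
        return out


@dataclass
class AssociationResult:
    snp_id: str
    chi2_statistic: float
    df: int
    p_value: float
    all_missing: bool = False
    low_expected: bool = False


def _call_rates(genotypes: np.ndarray, axis: int) -> np.ndarray:
    return 1.0 - np.mean(np.isnan(genotypes), axis=axis)


def sample_call_rate_filter(
    dataset: GenotypeDataset, threshold: float = 0.98
) -> tuple[GenotypeDataset, QcReport]:
    """Drop samples whose genotype call rate is not strictly above *threshold*."""
    rates = _call_rates(dataset.genotypes, axis=1)
    keep = rates > threshold
    report = QcReport(
        sample_call_rate=dict(zip(dataset.sample_ids, rates)),
        excluded_samples={
            sid: "CALL_RATE"
            for sid, k in zip(dataset.sample_ids, keep) if not k
        },
        n_snps_retained=dataset.n_snps,
    )
    if not keep.all():
        logger.info("sample call-rate filter removed %d sample(s)", (~keep).sum())
    return dataset.subset_samples(keep), report


def compute_maf(genotypes: np.ndarray) -> np.ndarray:
    """Minor allele frequency per SNP over non-missing alleles (column-wise)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        alt_freq = np.nanmean(genotypes, axis=0) / 2.0
    alt_freq = np.where(np.isnan(alt_freq), 0.0, alt_freq)
    return np.minimum(alt_freq, 1.0 - alt_freq)


def snp_filters(
    dataset: GenotypeDataset, min_call: float = 0.95, min_maf: float = 0.01
) -> tuple[GenotypeDataset, QcReport]:
    """Exclude SNPs in fixed order: Y chromosome, call rate, then MAF.

    Each excluded SNP records only the first filter that triggered.  MAF is
    computed on non-missing alleles of the (already sample-filtered) matrix.
    Raises ``ValueError`` if nothing survives.
    """
    call = _call_rates(dataset.genotypes, axis=0)
    maf = compute_maf(dataset.genotypes)
    y_mask = dataset.is_y_chrom()

    excluded: dict[str, str] = {}
    for i, sid in enumerate(dataset.snp_ids):
        if y_mask[i]:
            excluded[sid] = "Y_CHROM"
        elif call[i] < min_call:
            excluded[sid] = "CALL_RATE"
        elif maf[i] < min_maf:
            excluded[sid] = "MAF"
    keep = np.array([sid not in excluded for sid in dataset.snp_ids])
    if not keep.any():
        raise ValueError("all SNPs excluded by QC filters: empty analysis")
    report = QcReport(
        snp_call_rate=dict(zip(dataset.snp_ids, call)),
        snp_maf=dict(zip(dataset.snp_ids, maf)),
        excluded_snps=excluded,
        n_snps_retained=int(keep.sum()),
    )
    logger.info(
        "SNP filters: %d in, %d excluded (Y=%d, call=%d, MAF=%d), %d retained",
        dataset.n_snps, len(excluded),
        sum(r == "Y_CHROM" for r in excluded.values()),
        sum(r == "CALL_RATE" for r in excluded.values()),
        sum(r == "MAF" for r in excluded.values()),
        keep.sum(),
    )
    return dataset.subset_snps(keep), report


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two genotype columns, pairwise-complete."""
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 2:
        return 0.0
    x, y = a[ok], b[ok]
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(
    dataset: GenotypeDataset,
    r2_max: float = 0.5,
    window: int = 50,
    step: int = 5,
) -> tuple[GenotypeDataset, QcReport]:
    """Remove one SNP from every within-window pair with r² > *r2_max*.

    SNPs are processed per chromosome in position order with a sliding
    window of *window* SNPs advancing by *step*.  Within a window, violating
    pairs are resolved repeatedly until stable: the SNP with the lower call
    rate is removed; on a tie the one at the larger position goes.
    """
    order = np.lexsort((dataset.pos, dataset.chrom.astype(str)))
    call = _call_rates(dataset.genotypes, axis=0)
    removed: set[int] = set()

    chroms = dataset.chrom.astype(str)
    for chrom in sorted(set(chroms)):
        idx = [int(i) for i in order if chroms[i] == chrom]
        if len(idx) < 2 or window < 2:
            continue
        start = 0
        while start < len(idx):
            win = [i for i in idx[start:start + window] if i not in removed]
            changed = True
            while changed and len(win) >= 2:
                changed = False
                for a_pos in range(len(win)):
                    for b_pos in range(a_pos + 1, len(win)):
                        i, j = win[a_pos], win[b_pos]
                        r2 = _pairwise_r2(
                            dataset.genotypes[:, i], dataset.genotypes[:, j]
                        )
                        if r2 > r2_max:
                            if call[i] < call[j]:
                                drop = i
                            elif call[j] < call[i]:
                                drop = j
                            else:
                                drop = i if dataset.pos[i] > dataset.pos[j] else j
                            removed.add(drop)
                            win.remove(drop)
                            changed = True
                            break
                    if changed:
                        break
            start += step

    keep = np.array([i not in removed for i in range(dataset.n_snps)])
    report = QcReport(
        excluded_snps={dataset.snp_ids[i]: "LD_PRUNE" for i in sorted(removed)},
        n_snps_retained=int(keep.sum()),
    )
    if removed:
        logger.info("LD pruning removed %d SNP(s) at r2 > %g", len(removed), r2_max)
    return dataset.subset_snps(keep), report


def run_qc(
    dataset: GenotypeDataset,
    sample_call: float = 0.98,
    min_call: float = 0.95,
    min_maf: float = 0.01,
    r2_max: float = 0.5,
    window: int = 50,
    step: int = 5,
) -> tuple[GenotypeDataset, QcReport]:
    """Full QC chain: sample call rate → SNP filters → LD pruning."""
    ds, rep1 = sample_call_rate_filter(dataset, threshold=sample_call)
    ds, rep2 = snp_filters(ds, min_call=min_call, min_maf=min_maf)
    ds, rep3 = ld_prune(ds, r2_max=r2_max, window=window, step=step)
    return ds, rep1.merge(rep2).merge(rep3)


def _genotypic_table(col: np.ndarray, is_case: np.ndarray) -> np.ndarray:
    """2×3 case/control × genotype (0/1/2) counts over non-missing cells."""
    table = np.zeros((2, 3))
    ok = ~np.isnan(col)
    for row, mask in enumerate((is_case & ok, ~is_case & ok)):
        vals = col[mask].astype(int)
        for g in range(3):
            table[row, g] = np.sum(vals == g)
    return table


def pearson_chi2(table: np.ndarray) -> tuple[float, int]:
    """Pearson chi-square on a 2×c table after dropping zero-total columns.

    Degrees of freedom are the number of retained genotype columns minus one
    (two rows).  Returns ``(0.0, 0)`` for degenerate tables (a zero row or
    fewer than two non-empty columns).
    """
    table = np.asarray(table, dtype=float)
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2 or np.any(table.sum(axis=1) == 0):
        return 0.0, 0
    row = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    expected = row @ colsum / table.sum()
    chi2 = float(((table - expected) ** 2 / expected).sum())
    return chi2, table.shape[1] - 1


def genotypic_test(dataset: GenotypeDataset) -> list[AssociationResult]:
    """Per-SNP genotypic chi-square association (2×3 table, df ≤ 2).

    Genotype columns with zero total are dropped and the degrees of freedom
    reduced accordingly.  A SNP with every cell missing (or a degenerate
    table) gets p = 1 with a warning flag; tables with an expected count
    below 5 are flagged ``low_expected``.
    """
    is_case = dataset.is_case
    if not is_case.any() or is_case.all():
        raise ValueError("genotypic test requires >=1 case and >=1 control")
    results = []
    for j, snp_id in enumerate(dataset.snp_ids):
        col = dataset.genotypes[:, j]
        table = _genotypic_table(col, is_case)
        if table.sum() == 0:
            results.append(AssociationResult(snp_id, 0.0, 0, 1.0, all_missing=True))
            continue
        chi2, df = pearson_chi2(table)
        if df == 0:
            results.append(AssociationResult(snp_id, 0.0, 0, 1.0))
            continue
        nz = table[:, table.sum(axis=0) > 0]
        expected = nz.sum(axis=1, keepdims=True) @ nz.sum(axis=0, keepdims=True) / nz.sum()
        p = float(stats.chi2.sf(chi2, df))
        results.append(
            AssociationResult(
                snp_id, chi2, df, min(max(p, np.nextafter(0, 1)), 1.0),
                low_expected=bool((expected < 5).any()),
            )
        )
    return results


def threshold_snps(
    results: list[AssociationResult], alpha: float = 0.05
) -> list[str]:
    """SNP ids with association p strictly below *alpha*, in input order."""
    if not results:
        raise ValueError("no association results to threshold")
    return [r.snp_id for r in results if r.p_value < alpha]
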