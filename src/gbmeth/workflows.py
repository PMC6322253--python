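"""End-to-end convenience workflows over the analysis modules.

These functions wire the modules together the way the full study analysis
runs them: estimate the conversion error from the spike-in, derive the
coding-sequence background, classify genes in both conditions, compare
statuses, and relate methylation change to expression change.

Cross-condition status comparison classifies *both* conditions against a
single shared background (by default the control's coding background).
Classification answers "is this gene methylated above the wild-type coding
baseline?"; using each condition's own baseline would re-normalise away a
genome-wide loss, since a uniform dilution shrinks gene levels and the
background by the same factor and a pooled binomial over thousands of reads
would keep every originally-methylated gene significant. A shared baseline
makes status changes reflect absolute methylation loss, which is what the
knockdown contrast is about.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import association, caller, expression, quant
from .simulate import SimBundle


@dataclass
class ConditionCalls:
    p0: float
    nonconversion: quant.NonconversionEstimate
    calls_control: pd.DataFrame
    calls_kd: pd.DataFrame
    comparison: pd.DataFrame
    class_counts: dict[str, int]


def call_and_compare(
    allc_control: pd.DataFrame,
    allc_kd: pd.DataFrame,
    genes: pd.DataFrame,
    spikein_chrom: str,
    min_reads: int = 20,
    min_sites: int = 20,
    alpha: float = 0.05,
) -> ConditionCalls:
    """Classify both conditions against the shared control background.

    The background p0 is the control coding weighted level floored at the
    control spike-in non-conversion rate; the false-negative drop rule is
    applied per condition before comparison.
    """
    nonconv = quant.estimate_nonconversion(allc_control, spikein_chrom)
    p0 = caller.background_level(allc_control, genes, floor=max(nonconv.rate, 1e-6))
    kw = dict(min_reads=min_reads, min_sites=min_sites, alpha=alpha)
    calls_c = caller.drop_false_negatives(
        caller.classify_genes(allc_control, genes, p0, **kw)
    )
    calls_k = caller.drop_false_negatives(
        caller.classify_genes(allc_kd, genes, p0, **kw)
    )
    comparison, counts = caller.compare_status(calls_c, calls_k)
    return ConditionCalls(
        p0=p0, nonconversion=nonconv, calls_control=calls_c, calls_kd=calls_k,
        comparison=comparison, class_counts=counts,
    )


@dataclass
class AssociationSuite:
    calls: ConditionCalls
    summary: expression.ExpressionSummary
    de: pd.DataFrame
    regression: association.RegressionResult
    dd: association.DeltaDelta
    overlap: association.OverlapTable


def run_association_suite(bundle: SimBundle, m_tests: int = 1) -> AssociationSuite:
    """The full methylation-expression association analysis on one bundle.

    Uses the synthetic stand-in DE test (the real pipeline consumes an
    external DE results table instead). Regression and delta-delta use
    control-condition methylation and CPM-retained genes.
    """
    cc = call_and_compare(
        bundle.allc_control, bundle.allc_kd, bundle.genome.genes,
        bundle.genome.spikein_chrom,
    )
    ex = bundle.expression
    summary = expression.fpkm(ex.counts, ex.gene_lengths, ex.groups)
    de = expression.nb_moment_de_test(ex.counts, ex.groups)
    reg = association.level_regression(
        cc.calls_control, summary.group_means["control"], m_tests=m_tests
    )
    dd = association.delta_delta(cc.comparison, summary.log2fc, retained=summary.retained)
    overlap = association.overlap_analysis(cc.comparison, de["deg"])
    return AssociationSuite(
        calls=cc, summary=summary, de=de, regression=reg, dd=dd, overlap=overlap
    )
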