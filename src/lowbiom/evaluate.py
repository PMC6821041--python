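"""Accuracy, precision and composition diagnostics for mock-community runs.

*Accuracy* is the Bray-Curtis dissimilarity (BC) between a sample's
observed composition — aggregated to the taxa of its known expected
composition, with all unmatched abundance pooled into a single
"contaminant" bin — and that expected composition (0 = perfect
recovery, 1 = nothing recovered).  *Precision* is the BC between the
full OTU-level profiles of technical replicates (0 = perfectly
reproducible).

For unit-sum vectors BC = sum|x-y| / sum(x+y) reduces to 1 - sum min(x, y),
which is what makes contaminant removal provably helpful: zeroing only
taxa outside the expected composition and renormalising can never
increase the accuracy dissimilarity.

Also provided: observed richness at a taxonomic rank, the z-score matrix
used for abundance heatmaps, and the paired (Wilcoxon signed-rank) and
unpaired (Mann-Whitney U) tests used to compare treatment arms.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis as _sp_braycurtis

from .datamodel import ExpectedComposition, OtuTable, SampleMetadata, TaxonomyMap
from .contaminants import relative_abundance
from .exceptions import AnalysisError, ValidationError

CONTAMINANT_BIN = "__contaminant__"


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) of two non-negative vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("bray_curtis needs two equal-length 1-d vectors")
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("bray_curtis is defined for non-negative vectors")
    if x.sum() == 0 and y.sum() == 0:
        raise AnalysisError("Bray-Curtis undefined for two all-zero vectors")
    return float(_sp_braycurtis(x, y))


def match_expected_taxa(
    taxonomy: TaxonomyMap, expected: ExpectedComposition, otu_ids
) -> dict[str, list[str]]:
    """Resolve each expected taxon label to the OTUs whose lineage carries it.

    Matching is an exact rank-prefixed label match at the rank the
    expected table gives (``g__Burkholderia`` matches any OTU whose genus
    label is exactly that; species-level members match at species).
    """
    mapping: dict[str, list[str]] = {taxon: [] for taxon in expected.taxa}
    for otu in otu_ids:
        if otu not in taxonomy:
            continue
        lineage = taxonomy[otu]
        for taxon in expected.taxa:
            if taxon in lineage:
                mapping[taxon].append(otu)
    return mapping


def accuracy(
    table: OtuTable,
    taxonomy: TaxonomyMap,
    expected: dict[str, ExpectedComposition],
    metadata: SampleMetadata,
) -> pd.DataFrame:
    """Per-sample accuracy BC and mock read fraction.

    Each non-control sample whose ``community_id`` has an expected
    composition is aggregated to expected-taxon level plus one pooled
    contaminant bin, and compared to the expectation by Bray-Curtis.

    Returns a DataFrame indexed by sample with columns ``community_id``,
    ``density``, ``treatment``, ``accuracy_bci``, ``mock_fraction``.
    """
    if taxonomy is None or len(taxonomy) == 0:
        raise AnalysisError("accuracy requires OTU taxonomy annotations")
    meta = metadata.aligned_to(table)
    rel = relative_abundance(table)
    rows = []
    for sample in table.sample_ids:
        info = meta.frame.loc[sample]
        comp = expected.get(info["community_id"])
        if comp is None or info["is_control"]:
            continue
        mapping = match_expected_taxa(taxonomy, comp, table.otu_ids)
        col = rel[sample]
        observed = np.array(
            [col.loc[otus].sum() if otus else 0.0 for otus in mapping.values()]
        )
        contaminant = max(0.0, float(col.sum() - observed.sum()))
        obs_vec = np.append(observed, contaminant)
        exp_vec = np.append(comp.as_series().to_numpy(), 0.0)
        rows.append(
            (
                sample,
                info["community_id"],
                info["density"],
                info["treatment"],
                bray_curtis(obs_vec, exp_vec),
                float(observed.sum()),
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "community_id", "density", "treatment",
            "accuracy_bci", "mock_fraction",
        ],
    ).set_index("sample_id")
    return out


def precision(table: OtuTable, metadata: SampleMetadata) -> pd.DataFrame:
    """Bray-Curtis between technical replicates, per replicate group.

    Groups of two yield one row; larger groups yield all pairwise
    comparisons (their mean is the ``mean_bci`` of every row of the
    group).  Singleton groups are skipped with a warning.
    """
    meta = metadata.aligned_to(table)
    rel = relative_abundance(table)
    all_groups = meta.frame.groupby("replicate_group").groups
    small = [str(g) for g, idx in all_groups.items() if len(idx) < 2]
    if small:
        warnings.warn(f"singleton replicate groups skipped: {sorted(small)}",
                      stacklevel=2)
    rows = []
    for group, samples in meta.replicate_groups(min_size=2).items():
        info = meta.frame.loc[samples[0]]
        pair_bcis = []
        pairs = [
            (a, b)
            for i, a in enumerate(samples)
            for b in samples[i + 1:]
        ]
        for a, b in pairs:
            pair_bcis.append(bray_curtis(rel[a].to_numpy(), rel[b].to_numpy()))
        mean_bci = float(np.mean(pair_bcis))
        for (a, b), bci in zip(pairs, pair_bcis):
            rows.append(
                (group, a, b, info["community_id"], info["density"],
                 info["treatment"], bci, mean_bci)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "replicate_group", "sample_a", "sample_b", "community_id",
            "density", "treatment", "precision_bci", "mean_bci",
        ],
    )


def observed_richness(
    table: OtuTable, taxonomy: TaxonomyMap | None, rank: str = "g"
) -> pd.Series:
    """Number of distinct taxa at ``rank`` with >= 1 read, per sample.

    OTUs not resolved at the requested rank each count as their own
    unit (they are evidence of a distinct organism, just an unnamed one).
    """
    units = []
    for otu in table.otu_ids:
        name = taxonomy.rank_of(otu, rank) if taxonomy is not None else None
        units.append(f"{rank}:{name}" if name else f"otu:{otu}")
    present = (table.counts > 0)
    present.index = pd.Index(units)
    return present.groupby(level=0).any().sum(axis=0).rename("richness")


def zscore_matrix(rel: pd.DataFrame, top_n: int = 20) -> pd.DataFrame:
    """Across-sample z-scores of the ``top_n`` most abundant taxa.

    Taxa are ranked by mean relative abundance; each retained row is
    standardised with its sample mean and n-1 standard deviation.
    Constant rows (sd 0) become all-zero rows.
    """
    if rel.shape[1] < 2:
        raise AnalysisError("z-scores need >= 2 samples")
    order = rel.mean(axis=1).sort_values(ascending=False)
    kept = rel.loc[order.index[: int(top_n)]]
    means = kept.mean(axis=1)
    sds = kept.std(axis=1, ddof=1)
    z = kept.sub(means, axis=0).div(sds.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample comparison."""

    test: str
    statistic: float
    p_value: float
    n: int
    degenerate: bool = False

    def __str__(self) -> str:
        if self.degenerate:
            return f"{self.test}: degenerate (no informative differences)"
        return f"{self.test}: statistic={self.statistic:.4g}, p={self.p_value:.4g} (n={self.n})"


def compare_paired(a, b, min_pairs: int = 5) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped (Wilcoxon's rule); the p-value is exact
    for <= 25 informative pairs without ties, else the tie-corrected
    normal approximation.  All-zero differences yield a degenerate
    result rather than an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired comparison needs equal-length vectors")
    diffs = a - b
    n_nonzero = int((diffs != 0).sum())
    if n_nonzero == 0:
        return TestResult("wilcoxon_signed_rank", np.nan, np.nan, 0, degenerate=True)
    if n_nonzero < min_pairs:
        raise AnalysisError(
            f"need >= {min_pairs} nonzero paired differences, have {n_nonzero}"
        )
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                         method="auto")
    return TestResult("wilcoxon_signed_rank", float(res.statistic),
                      float(res.pvalue), n_nonzero)


def compare_unpaired(a, b, min_size: int = 3) -> TestResult:
    """Two-sided Mann-Whitney U test on two independent groups.

    Exact for small untied samples, tie-corrected normal approximation
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if a.size < min_size or b.size < min_size:
        raise AnalysisError(f"each group needs >= {min_size} values")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return TestResult("mann_whitney_u", float(res.statistic), float(res.pvalue),
                      int(a.size + b.size))
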