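"""Density-aware contaminant identification and the F1/F2/F3 filters.

Reagent and handling contaminants enter a sample at a roughly constant
absolute load, independent of how much bacterial DNA the sample itself
contains.  In relative-abundance space this leaves two fingerprints:

* **Feature 1** — an OTU's relative abundance is *negatively* rank-
  correlated with the sample's measured 16S input density: the less real
  signal, the larger the share the constant background claims.  An OTU is
  flagged when its Spearman rho is negative and significant (two-sided
  t-approximation on n - 2 df) and its prevalence passes the configured
  floor.
* **Feature 2** — an OTU is present in exactly one member of a
  technical-replicate group (a "singleton"): low-load contaminants drop
  in and out stochastically between parallel extractions of the same
  material.

Three filters act on the count table: ``F1`` zeroes Feature-1 OTUs in
all samples; ``F2`` zeroes an OTU only inside replicate groups where it
is a singleton; ``F3`` applies F1 and then re-derives and applies F2 on
the F1-filtered table.

The fitting interface follows the Model/Results convention:

>>> model = ContaminantModel(table, metadata)          # doctest: +SKIP
>>> res = model.fit()                                  # doctest: +SKIP
>>> print(res.summary())                               # doctest: +SKIP
>>> filtered = res.apply_filter("F3")                  # doctest: +SKIP
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import OtuTable, SampleMetadata
from .exceptions import AnalysisError, ValidationError

FILTER_MODES = ("F1", "F2", "F3")

#: fewest non-control, positive-density samples a correlation needs
MIN_SAMPLES_FEATURE1 = 3


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds governing Feature calls.

    alpha
        Two-sided significance threshold for Feature 1 (default 0.05,
        applied to raw p-values unless ``multiple_testing="benjamini_hochberg"``).
    min_prevalence
        Minimum fraction of samples with a nonzero count for an OTU to be
        eligible for Feature 1 (default 0: every OTU is tested).
    presence_threshold
        Definition of "present" for Feature 2: an integer >= 1 is a
        minimum read count; a float in (0, 1) is a minimum within-sample
        relative abundance (e.g. 1e-3).
    multiple_testing
        ``"none"`` or ``"benjamini_hochberg"``.
    exclude_controls
        Leave negative controls out of the correlation fit (they are
        still subject to filtering).
    """

    alpha: float = 0.05
    min_prevalence: float = 0.0
    presence_threshold: float = 1
    multiple_testing: str = "none"
    exclude_controls: bool = True

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 <= self.min_prevalence <= 1.0:
            raise ValidationError("min_prevalence must be in [0, 1]")
        t = self.presence_threshold
        if not ((t >= 1 and float(t).is_integer()) or 0.0 < t < 1.0):
            raise ValidationError(
                "presence_threshold must be an integer >= 1 (reads) or a "
                f"fraction in (0, 1), got {t}"
            )
        if self.multiple_testing not in ("none", "benjamini_hochberg"):
            raise ValidationError(
                f"unknown multiple_testing {self.multiple_testing!r}"
            )

    @property
    def presence_is_fraction(self) -> bool:
        return 0.0 < self.presence_threshold < 1.0


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Convert counts to within-sample relative abundances.

    Every sample column sums to 1; a zero-depth sample yields an all-zero
    column and a warning (it carries no compositional information).
    """
    depths = table.sample_depths()
    empty = depths[depths == 0].index.tolist()
    if empty:
        warnings.warn(
            f"samples with zero total reads left as all-zero columns: {empty}",
            stacklevel=2,
        )
    safe = depths.replace(0, 1)
    return table.counts.div(safe, axis=1).astype(float)


def prevalence(table: OtuTable) -> pd.Series:
    """Fraction of samples in which each OTU has a nonzero count."""
    return (table.counts > 0).mean(axis=1)


def _spearman_to_vector(matrix: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Spearman rho and two-sided p of ``matrix`` against ``y``.

    Average ranks for ties; p from the t approximation on n - 2 df.
    Zero-variance rows get (nan, nan).
    """
    n = matrix.shape[1]
    ry = stats.rankdata(y)
    rx = stats.rankdata(matrix, axis=1)
    rx_c = rx - rx.mean(axis=1, keepdims=True)
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum(axis=1) * (ry_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx_c @ ry_c) / denom
    rho = np.where(denom == 0, np.nan, np.clip(rho, -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(rho), np.nan, np.where(np.abs(rho) == 1.0, 0.0, p))
    return rho, p


def feature1(
    rel: pd.DataFrame,
    meta: SampleMetadata,
    config: FilterConfig = FilterConfig(),
    table: OtuTable | None = None,
) -> pd.DataFrame:
    """Per-OTU density correlation and the Feature-1 flag.

    Parameters
    ----------
    rel
        Relative-abundance matrix (OTUs x samples).
    meta
        Metadata covering every column of ``rel``.
    config
        Thresholds; see :class:`FilterConfig`.
    table
        Optional count table used for the prevalence column; when absent,
        prevalence is computed from nonzero relative abundances.

    Returns
    -------
    DataFrame indexed by OTU with columns ``rho``, ``p_value``,
    ``p_adjusted``, ``prevalence``, ``feature1``.
    """
    sub = meta.frame.loc[[s for s in rel.columns if s in meta.frame.index]]
    if len(sub) < len(rel.columns):
        missing = set(rel.columns) - set(sub.index)
        raise ValidationError(f"samples without metadata: {sorted(missing)}")
    keep = sub["density"] > 0
    if config.exclude_controls:
        keep &= ~sub["is_control"]
    used = sub.index[keep]
    if len(used) < MIN_SAMPLES_FEATURE1:
        raise AnalysisError(
            f"Feature 1 needs >= {MIN_SAMPLES_FEATURE1} non-control samples "
            f"with density > 0; have {len(used)}"
        )
    dens = sub.loc[used, "density"].to_numpy()
    if np.unique(dens).size < 2:
        raise AnalysisError("Feature 1 needs at least two distinct densities")

    matrix = rel[used].to_numpy(dtype=float)
    rho, p = _spearman_to_vector(matrix, dens)

    if config.multiple_testing == "benjamini_hochberg":
        p_adj = np.full_like(p, np.nan)
        ok = ~np.isnan(p)
        if ok.any():
            p_adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    else:
        p_adj = p.copy()

    if table is not None:
        prev = prevalence(table).to_numpy()
    else:
        prev = (rel.to_numpy() > 0).mean(axis=1)

    with np.errstate(invalid="ignore"):
        flag = (rho < 0) & (p_adj <= config.alpha) & (prev >= config.min_prevalence)
    flag = np.where(np.isnan(rho), False, flag).astype(bool)
    return pd.DataFrame(
        {
            "rho": rho,
            "p_value": p,
            "p_adjusted": p_adj,
            "prevalence": prev,
            "feature1": flag,
        },
        index=rel.index,
    )


def presence_matrix(table: OtuTable, config: FilterConfig) -> pd.DataFrame:
    """Boolean OTU x sample matrix of "present" under the configured rule."""
    if config.presence_is_fraction:
        return relative_abundance(table) >= config.presence_threshold
    return table.counts >= int(config.presence_threshold)


def feature2(
    table: OtuTable,
    meta: SampleMetadata,
    config: FilterConfig = FilterConfig(),
) -> pd.Series:
    """Replicate-singleton detection (Feature 2).

    For every replicate group of >= 2 samples, an OTU is a singleton in
    that group iff it is present in exactly one member.  Returns a Series
    indexed by OTU whose values are frozensets of group ids where the OTU
    is a singleton.  Groups of one sample are skipped with a warning.
    """
    meta = meta.aligned_to(table)
    all_groups = meta.frame.groupby("replicate_group").groups
    small = [g for g, idx in all_groups.items() if len(idx) < 2]
    if small:
        warnings.warn(
            f"replicate groups with a single sample skipped: {sorted(map(str, small))}",
            stacklevel=2,
        )
    groups = meta.replicate_groups(min_size=2)
    if not groups:
        raise AnalysisError("no replicate groups with >= 2 samples")
    present = presence_matrix(table, config)
    singleton_sets: list[set[str]] = [set() for _ in table.otu_ids]
    for group, samples in groups.items():
        hits = present[samples].sum(axis=1).to_numpy()
        for i in np.flatnonzero(hits == 1):
            singleton_sets[i].add(group)
    return pd.Series(
        [frozenset(s) for s in singleton_sets], index=table.counts.index,
        name="feature2_groups",
    )


def apply_filter(
    table: OtuTable,
    calls: "ContaminantResults",
    mode: str,
) -> tuple[OtuTable, pd.DataFrame]:
    """Remove flagged reads; returns the filtered table and a removal report.

    ``F1`` zeroes Feature-1 OTUs everywhere; ``F2`` zeroes an OTU only in
    replicate groups where it is a singleton; ``F3`` applies F1 then
    recomputes Feature 2 on the filtered table and applies F2.  The
    report lists one row per (otu, sample) cell emptied, with the reads
    removed and the reason.  Unflagged cells are untouched.
    """
    if mode not in FILTER_MODES:
        raise ValueError(f"unknown filter mode {mode!r}; choose from {FILTER_MODES}")
    if list(table.otu_ids) != list(calls.calls.index):
        raise ValidationError("calls were computed on a different OTU set")

    counts = table.counts.copy()
    report_rows: list[tuple[str, str, int, str]] = []

    if mode in ("F1", "F3"):
        flagged = calls.calls.index[calls.calls["feature1"]]
        for otu in flagged:
            row = counts.loc[otu]
            for sample in row.index[row > 0]:
                report_rows.append((otu, sample, int(row[sample]), "F1"))
            counts.loc[otu] = 0

    if mode in ("F2", "F3"):
        working = OtuTable(counts)
        if mode == "F3":
            # re-derive singletons on the F1-filtered table
            f2_groups = feature2(working, calls.metadata, calls.config)
        else:
            f2_groups = calls.feature2_groups
        group_samples = calls.metadata.aligned_to(working).replicate_groups(min_size=2)
        for otu, groups in f2_groups.items():
            for group in groups:
                for sample in group_samples.get(group, []):
                    reads = int(counts.at[otu, sample])
                    if reads > 0:
                        report_rows.append((otu, sample, reads, "F2"))
                        counts.at[otu, sample] = 0

    report = pd.DataFrame(
        report_rows, columns=["otu_id", "sample_id", "reads_removed", "reason"]
    )
    return OtuTable(counts), report


class ContaminantModel:
    """Contaminant feature model for one OTU table + metadata pairing.

    Parameters
    ----------
    table
        Read counts (OTUs x samples).
    metadata
        Per-sample density, replicate structure, control flags; must
        cover every sample in ``table``.
    config
        Feature thresholds (default :class:`FilterConfig`).
    """

    def __init__(
        self,
        table: OtuTable,
        metadata: SampleMetadata,
        config: FilterConfig = FilterConfig(),
    ):
        self.table = table
        self.metadata = metadata.aligned_to(table)
        self.config = config

    @classmethod
    def from_files(cls, table_path, metadata_path, config: FilterConfig = FilterConfig()):
        from .io import read_metadata, read_otu_table

        table, _ = read_otu_table(table_path)
        return cls(table, read_metadata(metadata_path), config)

    def fit(self) -> "ContaminantResults":
        """Compute Features 1 and 2 for every OTU."""
        rel = relative_abundance(self.table)
        f1 = feature1(rel, self.metadata, self.config, table=self.table)
        f2 = feature2(self.table, self.metadata, self.config)
        calls = f1.copy()
        calls["feature2_groups"] = f2
        calls["label"] = np.where(
            calls["feature1"] | (f2.map(len) > 0), "contaminant", "retained"
        )
        return ContaminantResults(self, calls)


@dataclass
class ContaminantResults:
    """Fitted per-OTU contaminant statistics and filter application.

    ``calls`` is a DataFrame indexed by OTU id with columns ``rho``,
    ``p_value``, ``p_adjusted``, ``prevalence``, ``feature1``,
    ``feature2_groups`` (frozenset of replicate-group ids) and ``label``
    (``contaminant`` / ``retained``).
    """

    model: ContaminantModel
    calls: pd.DataFrame = field(repr=False)

    @property
    def table(self) -> OtuTable:
        return self.model.table

    @property
    def metadata(self) -> SampleMetadata:
        return self.model.metadata

    @property
    def config(self) -> FilterConfig:
        return self.model.config

    @property
    def feature2_groups(self) -> pd.Series:
        return self.calls["feature2_groups"]

    def apply_filter(self, mode: str = "F3") -> tuple[OtuTable, pd.DataFrame]:
        """Filtered table + removal report for mode ``F1``/``F2``/``F3``."""
        return apply_filter(self.table, self, mode)

    def flagged(self, feature: str = "any") -> list[str]:
        """OTU ids flagged by ``"feature1"``, ``"feature2"`` or ``"any"``."""
        if feature == "feature1":
            mask = self.calls["feature1"]
        elif feature == "feature2":
            mask = self.feature2_groups.map(len) > 0
        elif feature == "any":
            mask = self.calls["label"] == "contaminant"
        else:
            raise ValueError(f"unknown feature selector {feature!r}")
        return list(self.calls.index[mask])

    def to_frame(self) -> pd.DataFrame:
        """Flat, TSV-friendly view (feature2 groups joined with ';')."""
        out = self.calls.drop(columns=["feature2_groups"]).copy()
        out.insert(
            4,
            "feature2_groups",
            self.feature2_groups.map(lambda s: ";".join(sorted(s))),
        )
        out.index.name = "otu_id"
        return out

    def summary(self) -> str:
        """Human-readable overview of the fit."""
        c = self.calls
        n_f1 = int(c["feature1"].sum())
        n_f2 = int((self.feature2_groups.map(len) > 0).sum())
        n_both = int((c["feature1"] & (self.feature2_groups.map(len) > 0)).sum())
        n_cont = int((c["label"] == "contaminant").sum())
        total = self.table.total_reads()
        f1_reads = int(self.table.counts.loc[c["feature1"]].to_numpy().sum())
        lines = [
            "Contaminant feature model",
            "=" * 60,
            f"OTUs: {len(c)}    samples: {len(self.table.sample_ids)}",
            f"alpha: {self.config.alpha}   multiple testing: "
            f"{self.config.multiple_testing}   min prevalence: "
            f"{self.config.min_prevalence}",
            f"presence threshold: {self.config.presence_threshold}"
            + (" (relative abundance)" if self.config.presence_is_fraction
               else " (reads)"),
            "-" * 60,
            f"Feature 1 (density-anticorrelated): {n_f1} OTUs "
            f"({f1_reads / total:.1%} of reads)" if total else
            f"Feature 1 (density-anticorrelated): {n_f1} OTUs",
            f"Feature 2 (replicate singletons):   {n_f2} OTUs",
            f"both features:                      {n_both} OTUs",
            f"labelled contaminant:               {n_cont} / {len(c)} OTUs",
            "=" * 60,
        ]
        return "\n".join(lines)

    def plot_density_correlation(self, ax=None):
        """Scatter of per-OTU rho against prevalence, coloured by flag."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        c = self.calls.dropna(subset=["rho"])
        flagged = c["feature1"]
        ax.scatter(c.loc[~flagged, "rho"], c.loc[~flagged, "prevalence"],
                   s=12, alpha=0.6, label="retained")
        ax.scatter(c.loc[flagged, "rho"], c.loc[flagged, "prevalence"],
                   s=12, alpha=0.8, color="crimson", label="Feature 1")
        ax.axvline(0.0, lw=0.8, color="grey")
        ax.set_xlabel("Spearman rho vs input density")
        ax.set_ylabel("prevalence")
        ax.legend(frameon=False)
        return ax
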