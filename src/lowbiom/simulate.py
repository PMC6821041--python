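"""Synthetic mock-community dilution series with reagent contamination.

The generator reproduces the statistical structure of a low-biomass 16S
benchmarking experiment:

* three mock communities of known composition (equimolar 3-species,
  50/50 2-species, and a staggered 5-species community at
  55/24/15/5.5/0.5%),
* a tenfold dilution ladder spanning 8E+02 to 8E+09 16S copies/ml,
* a *density-independent* contaminant background: each extraction
  receives a lognormal copy load per background OTU whose mean does not
  scale with the sample's own density — so contaminants take over in
  relative abundance exactly as real reagent contamination does,
* technical-replicate pairs (independent extractions of the same
  material), no-template controls, an optional tenfold concentration
  treatment, and fixed-depth multinomial read sampling.

The background pool defaults to 600 OTUs with log-uniform mean loads
spanning three decades and a total of 2E+05 copies per extraction,
placing the density at which contaminant and sample-derived loads are
equal at 8E+05 copies/ml.  In expectation the contaminant read fraction
at sample density D is ``B / (B + D * v)`` with B the summed background
mean and v the extracted volume (:func:`expected_contaminant_fraction`).

Every simulated dataset ships with ground-truth member/contaminant
labels (:class:`SimulationTruth`), so filter performance can be scored
exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .datamodel import (
    ExpectedComposition,
    Lineage,
    OtuTable,
    SampleMetadata,
    TaxonomyMap,
)
from .exceptions import ValidationError

# mock community members: expected-taxon label -> (otu id, lineage)
MOCK_MEMBERS: dict[str, tuple[str, str]] = {
    "s__Pseudomonas aeruginosa": (
        "OTU_M1",
        "k__Bacteria; p__Proteobacteria; c__Gammaproteobacteria; "
        "o__Pseudomonadales; f__Pseudomonadaceae; g__Pseudomonas; "
        "s__Pseudomonas aeruginosa",
    ),
    "s__Burkholderia multivorans": (
        "OTU_M2",
        "k__Bacteria; p__Proteobacteria; c__Betaproteobacteria; "
        "o__Burkholderiales; f__Burkholderiaceae; g__Burkholderia; "
        "s__Burkholderia multivorans",
    ),
    "s__Stenotrophomonas maltophilia": (
        "OTU_M3",
        "k__Bacteria; p__Proteobacteria; c__Gammaproteobacteria; "
        "o__Xanthomonadales; f__Xanthomonadaceae; g__Stenotrophomonas; "
        "s__Stenotrophomonas maltophilia",
    ),
    "s__Staphylococcus aureus": (
        "OTU_M4",
        "k__Bacteria; p__Firmicutes; c__Bacilli; o__Bacillales; "
        "f__Staphylococcaceae; g__Staphylococcus; s__Staphylococcus aureus",
    ),
    "s__Fusobacterium nucleatum": (
        "OTU_M5",
        "k__Bacteria; p__Fusobacteria; c__Fusobacteriia; o__Fusobacteriales; "
        "f__Fusobacteriaceae; g__Fusobacterium; s__Fusobacterium nucleatum",
    ),
    "s__Bacillus halodurans": (
        "OTU_M6",
        "k__Bacteria; p__Firmicutes; c__Bacilli; o__Bacillales; "
        "f__Bacillaceae; g__Bacillus; s__Bacillus halodurans",
    ),
    "s__Streptococcus anginosus": (
        "OTU_M7",
        "k__Bacteria; p__Firmicutes; c__Bacilli; o__Lactobacillales; "
        "f__Streptococcaceae; g__Streptococcus; s__Streptococcus anginosus",
    ),
    "s__Gemella haemolysans": (
        "OTU_M8",
        "k__Bacteria; p__Firmicutes; c__Bacilli; o__Bacillales; "
        "f__Bacillales_fam_XI; g__Gemella; s__Gemella haemolysans",
    ),
}

DEFAULT_COMMUNITIES: dict[str, dict[str, float]] = {
    "mock1": {
        "s__Pseudomonas aeruginosa": 1 / 3,
        "s__Burkholderia multivorans": 1 / 3,
        "s__Stenotrophomonas maltophilia": 1 / 3,
    },
    "mock2": {
        "s__Pseudomonas aeruginosa": 0.5,
        "s__Burkholderia multivorans": 0.5,
    },
    "mock3": {
        "s__Staphylococcus aureus": 0.55,
        "s__Fusobacterium nucleatum": 0.24,
        "s__Bacillus halodurans": 0.15,
        "s__Streptococcus anginosus": 0.055,
        "s__Gemella haemolysans": 0.005,
    },
}

#: tenfold ladder, 8E+02 .. 8E+09 copies/ml
DEFAULT_DENSITIES: tuple[float, ...] = tuple(8.0 * 10.0**k for k in range(2, 10))

# dominant reagent-contaminant genera, assigned to the largest pool loads
NAMED_CONTAMINANT_GENERA = (
    "Acinetobacter", "Pseudomonas", "Rhizobium", "Comamonas",
    "Novosphingobium", "Sphingobium", "Paracoccus", "Stenotrophomonas",
    "Bifidobacterium", "Brevundimonas", "Sphingomonas", "Bradyrhizobium",
    "Dietzia", "Massilia", "Shewanella",
)

# airway commensal genera used for BALF-like cohorts
AIRWAY_TAXA = (
    "g__Prevotella", "g__Veillonella", "g__Streptococcus", "g__Neisseria",
    "g__Haemophilus", "g__Rothia", "g__Fusobacterium", "g__Gemella",
)


def build_default_pool(
    n_taxa: int = 600, decades: float = 3.0, total_copies: float = 2e5
) -> pd.Series:
    """Default contaminant background: mean copies per extraction, per taxon.

    Mean loads are log-uniformly spaced over ``decades`` orders of
    magnitude and scaled to sum to ``total_copies``.  The largest loads
    carry the genus names that dominate reagent contamination; the long
    tail gets anonymous placeholder genera.
    """
    if n_taxa < 1 or total_copies <= 0:
        raise ValidationError("pool needs >= 1 taxon and a positive total load")
    means = np.logspace(0.0, decades, n_taxa)
    means = means / means.sum() * total_copies
    means = means[::-1]  # descending: named genera first
    names = [
        NAMED_CONTAMINANT_GENERA[i]
        if i < len(NAMED_CONTAMINANT_GENERA)
        else f"Reagent_{i + 1:03d}"
        for i in range(n_taxa)
    ]
    return pd.Series(means, index=names, name="mean_copies")


class SimulatedDataset(NamedTuple):
    table: OtuTable
    metadata: SampleMetadata
    taxonomy: TaxonomyMap
    expected: dict[str, ExpectedComposition]
    truth: "SimulationTruth"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic dilution series.

    Defaults reproduce the benchmark design: 3 communities x 8 densities
    x 2 technical replicates at 20 000 reads, 0.25 ml of sample entering
    each extraction, 4 duplicate no-template control pairs, and the
    600-taxon background described in the module docstring.
    """

    communities: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COMMUNITIES.items()}
    )
    densities: tuple[float, ...] = DEFAULT_DENSITIES
    contaminant_pool: pd.Series = field(default_factory=build_default_pool)
    pool_sigma: float = 1.0
    depth: int = 20_000
    replicates: int = 2
    template_volume_ml: float = 0.25
    concentration_factor: float = 10.0
    include_concentrated: bool = False
    n_control_pairs: int = 4
    pcr_dirichlet: float | None = None
    seed: int | None = None

    def __post_init__(self):
        if not self.communities:
            raise ValidationError("at least one community is required")
        for cid, comp in self.communities.items():
            if not comp:
                raise ValidationError(f"community {cid!r} has no members")
            total = sum(comp.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"community {cid!r} fractions sum to {total}, not 1"
                )
            unknown = set(comp) - set(MOCK_MEMBERS)
            if unknown:
                raise ValidationError(
                    f"community {cid!r} has unknown member taxa: {sorted(unknown)}"
                )
        if len(self.densities) == 0 or any(d <= 0 for d in self.densities):
            raise ValidationError("densities must be positive")
        if self.depth <= 0:
            raise ValidationError("depth must be > 0")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if self.pool_sigma <= 0:
            raise ValidationError("pool_sigma must be > 0")
        if self.template_volume_ml <= 0:
            raise ValidationError("template_volume_ml must be > 0")
        if self.concentration_factor <= 0:
            raise ValidationError("concentration_factor must be > 0")
        if (self.contaminant_pool < 0).any():
            raise ValidationError("contaminant pool means must be >= 0")

    @property
    def background_total(self) -> float:
        """B: summed mean background copies per extraction."""
        return float(self.contaminant_pool.sum())


@dataclass
class SimulationTruth:
    """Ground truth attached to a simulated dataset.

    ``labels`` is OTU x community ("member"/"contaminant"); a taxon can
    be a member of one community and a contaminant everywhere else.
    ``sample_loads`` records the realised member and contaminant copy
    loads of each extraction.
    """

    labels: pd.DataFrame
    sample_loads: pd.DataFrame
    config: SimulationConfig

    def member_otus(self, community_id: str) -> list[str]:
        col = self.labels[community_id]
        return list(col.index[col == "member"])

    def contaminant_mask(self, community_id: str) -> pd.Series:
        return self.labels[community_id] == "contaminant"

    def contaminant_read_fraction(
        self, table: OtuTable, metadata: SampleMetadata
    ) -> pd.Series:
        """Per-sample fraction of reads from truth-labelled contaminants."""
        meta = metadata.aligned_to(table)
        depths = table.sample_depths().astype(float)
        out = {}
        for sample in table.sample_ids:
            community = meta.frame.loc[sample, "community_id"]
            mask = self.contaminant_mask(community).reindex(
                table.otu_ids, fill_value=True
            )
            reads = table.counts.loc[mask.to_numpy(), sample].sum()
            out[sample] = reads / depths[sample] if depths[sample] else np.nan
        return pd.Series(out, name="contaminant_read_fraction")


def expected_contaminant_fraction(density: float, cfg: SimulationConfig) -> float:
    """Expected contaminant read fraction ``B / (B + density * v)``.

    B is the summed mean background load per extraction and v the sample
    volume extracted; the fraction tends to 1 as density falls to 0 and
    decreases strictly with density.
    """
    if density < 0:
        raise ValidationError("density must be >= 0")
    b = cfg.background_total
    return b / (b + density * cfg.template_volume_ml)


def _pool_frame(cfg: SimulationConfig) -> pd.DataFrame:
    pool = cfg.contaminant_pool
    return pd.DataFrame(
        {
            "otu_id": [f"OTU_C{i + 1:04d}" for i in range(len(pool))],
            "genus": pool.index,
            "mean_copies": pool.to_numpy(dtype=float),
        }
    )


def _build_taxonomy(pool: pd.DataFrame) -> TaxonomyMap:
    strings = {otu: lin for _, (otu, lin) in MOCK_MEMBERS.items()}
    for _, row in pool.iterrows():
        strings[row["otu_id"]] = f"k__Bacteria; g__{row['genus']}"
    return TaxonomyMap.from_strings(strings)


def _one_sample(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    member_fracs: np.ndarray,
    pool_means: np.ndarray,
    effective_density: float,
) -> tuple[np.ndarray, float, float]:
    """Draw one extraction + sequencing run.

    Returns (read counts over [members..., pool...], member load,
    contaminant load).
    """
    member_load = effective_density * cfg.template_volume_ml * member_fracs
    sigma = cfg.pool_sigma
    mu = np.log(np.where(pool_means > 0, pool_means, 1.0)) - sigma**2 / 2
    cont_load = np.where(
        pool_means > 0, rng.lognormal(mean=mu, sigma=sigma), 0.0
    )
    loads = np.concatenate([member_load, cont_load])
    total = loads.sum()
    if total <= 0:
        return np.zeros(loads.size, dtype=np.int64), 0.0, 0.0
    p = loads / total
    if cfg.pcr_dirichlet is not None:
        # optional amplification-bias knob: jitter probabilities
        alpha = np.clip(p * cfg.pcr_dirichlet, 1e-12, None)
        p = rng.dirichlet(alpha)
    counts = rng.multinomial(cfg.depth, p)
    return counts, float(member_load.sum()), float(cont_load.sum())


def simulate_dataset(
    cfg: SimulationConfig | None = None, seed: int | None = None
) -> SimulatedDataset:
    """Generate the full dilution-series dataset with ground truth.

    For each community x density x replicate (plus an optional
    concentrated arm and no-template control pairs) the member copy load
    is ``density * template_volume_ml * fraction`` (deterministic), the
    background load is an independent lognormal draw per pool taxon and
    extraction, and reads are multinomial at fixed depth.  Metadata
    ``density`` records the *nominal* sample density; the concentration
    factor enters the load computation only.  Deterministic given the
    seed.
    """
    cfg = cfg if cfg is not None else SimulationConfig()
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    pool = _pool_frame(cfg)
    pool_means = pool["mean_copies"].to_numpy()
    member_labels = list(MOCK_MEMBERS)
    member_otus = [MOCK_MEMBERS[t][0] for t in member_labels]
    otu_ids = member_otus + pool["otu_id"].tolist()

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    load_rows = []

    def add_sample(sid, community, fracs, nominal_density, group, treatment,
                   is_control, factor):
        counts, m_load, c_load = _one_sample(
            rng, cfg, fracs, pool_means, nominal_density * factor
        )
        columns[sid] = counts
        meta_rows.append((sid, nominal_density, group, community, treatment,
                          is_control))
        load_rows.append((sid, m_load, c_load))

    treatments = [("none", 1.0)]
    if cfg.include_concentrated:
        treatments.append(("concentrated", cfg.concentration_factor))
    for community, comp in cfg.communities.items():
        fracs = np.array([comp.get(t, 0.0) for t in member_labels])
        for treatment, factor in treatments:
            suffix = "" if treatment == "none" else "_conc"
            for di, density in enumerate(cfg.densities):
                group = f"{community}_d{di + 1}{suffix}"
                for r in range(cfg.replicates):
                    add_sample(
                        f"{group}_r{r + 1}", community, fracs, density,
                        group, treatment, False, factor,
                    )
    zero_fracs = np.zeros(len(member_labels))
    for i in range(cfg.n_control_pairs):
        group = f"NTC{i + 1}"
        for r in range(2):
            add_sample(f"{group}_r{r + 1}", "NTC", zero_fracs, 0.0, group,
                       "none", True, 1.0)

    table = OtuTable(pd.DataFrame(columns, index=otu_ids))
    metadata = SampleMetadata(
        pd.DataFrame(
            meta_rows,
            columns=["sample_id", "density", "replicate_group", "community_id",
                     "treatment", "is_control"],
        )
    )
    taxonomy = _build_taxonomy(pool)
    expected = {
        cid: ExpectedComposition(cid, {t: f / sum(comp.values())
                                       for t, f in comp.items()})
        for cid, comp in cfg.communities.items()
    }
    label_cols = {}
    for cid, comp in cfg.communities.items():
        members = {MOCK_MEMBERS[t][0] for t in comp}
        label_cols[cid] = ["member" if o in members else "contaminant"
                           for o in otu_ids]
    label_cols["NTC"] = ["contaminant"] * len(otu_ids)
    truth = SimulationTruth(
        labels=pd.DataFrame(label_cols, index=otu_ids),
        sample_loads=pd.DataFrame(
            load_rows, columns=["sample_id", "member_copies", "contaminant_copies"]
        ).set_index("sample_id"),
        config=cfg,
    )
    return SimulatedDataset(table, metadata, taxonomy, expected, truth)


def simulate_balf_like(
    cfg: SimulationConfig | None = None,
    n_subjects: int = 25,
    replicates: int = 2,
    density_range: tuple[float, float] = (1e5, 4.2e8),
    seed: int | None = None,
) -> SimulatedDataset:
    """Heterogeneous-density cohort without a known expected composition.

    Each subject gets a density drawn log-uniformly over
    ``density_range`` (default the 1E+05 to 4.2E+08 copies/ml range seen
    in clinical lavage fluid) and a private airway community drawn from
    a flat Dirichlet over eight commensal genera; technical replicates
    share both.  The contaminant background and sequencing model are the
    ones in ``cfg``.  Returns the usual dataset tuple; ``expected`` is
    empty (the composition is unknown by design) but truth labels are
    attached for benchmarking.
    """
    cfg = cfg if cfg is not None else SimulationConfig()
    if n_subjects * replicates < 2:
        raise ValidationError("need at least 2 samples")
    lo, hi = density_range
    if not 0 < lo < hi:
        raise ValidationError("density_range must satisfy 0 < low < high")
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    pool = _pool_frame(cfg)
    pool_means = pool["mean_copies"].to_numpy()
    airway_otus = [f"OTU_A{i + 1}" for i in range(len(AIRWAY_TAXA))]
    otu_ids = airway_otus + pool["otu_id"].tolist()

    columns = {}
    meta_rows = []
    load_rows = []
    for s in range(n_subjects):
        density = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        fracs = rng.dirichlet(np.ones(len(AIRWAY_TAXA)))
        group = f"BALF{s + 1:03d}"
        for r in range(replicates):
            sid = f"{group}_r{r + 1}"
            counts, m_load, c_load = _one_sample(rng, cfg, fracs, pool_means,
                                                 density)
            columns[sid] = counts
            meta_rows.append((sid, density, group, "balf", "none", False))
            load_rows.append((sid, m_load, c_load))

    table = OtuTable(pd.DataFrame(columns, index=otu_ids))
    metadata = SampleMetadata(
        pd.DataFrame(
            meta_rows,
            columns=["sample_id", "density", "replicate_group", "community_id",
                     "treatment", "is_control"],
        )
    )
    strings = {
        otu: f"k__Bacteria; {label}" for otu, label in zip(airway_otus, AIRWAY_TAXA)
    }
    for _, row in pool.iterrows():
        strings[row["otu_id"]] = f"k__Bacteria; g__{row['genus']}"
    taxonomy = TaxonomyMap.from_strings(strings)
    labels = pd.DataFrame(
        {"balf": ["member"] * len(airway_otus) + ["contaminant"] * len(pool)},
        index=otu_ids,
    )
    truth = SimulationTruth(
        labels=labels,
        sample_loads=pd.DataFrame(
            load_rows, columns=["sample_id", "member_copies", "contaminant_copies"]
        ).set_index("sample_id"),
        config=cfg,
    )
    return SimulatedDataset(table, metadata, taxonomy, {}, truth)


def with_seed(cfg: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``cfg`` with a different seed."""
    return replace(cfg, seed=seed)
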