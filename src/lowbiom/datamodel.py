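"""Core in-memory containers for amplicon count data and sample annotations.

The central objects are:

* :class:`OtuTable` — a non-negative integer count matrix, OTUs (rows) by
  samples (columns), with unique string identifiers on both axes.
* :class:`SampleMetadata` — one row per sample carrying the measured 16S
  density (copies/ml), the technical-replicate group, the community or
  cohort the sample belongs to, its treatment and whether it is a
  negative control.
* :class:`TaxonomyMap` — optional OTU -> lineage annotation using
  rank-prefixed labels (``k__``, ``p__``, ``c__``, ``o__``, ``f__``,
  ``g__``, ``s__``); OTUs may be resolved at mixed depths.
* :class:`ExpectedComposition` — the known relative-abundance vector of a
  mock community, used as the accuracy reference.

Counts are raw reads; relative abundances are a derived quantity (see
:func:`lowbiom.contaminants.relative_abundance`) and are never stored
back into an :class:`OtuTable`.
"""
from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

RANKS = ("k", "p", "c", "o", "f", "g", "s")
TREATMENTS = ("none", "concentrated")


class OtuTable:
    """Validated OTU-by-sample read-count matrix.

    Parameters
    ----------
    counts
        DataFrame of read counts with OTU identifiers as the index and
        sample identifiers as the columns.  Values must be non-negative
        integers (an integer-valued float dtype is accepted and cast).

    Notes
    -----
    Rows with zero total count are legal and preserved: "this OTU was
    observed nowhere" is information the filters rely on when tables are
    compared before/after removal.
    """

    def __init__(self, counts: pd.DataFrame):
        counts = pd.DataFrame(counts).copy()
        if counts.shape[0] == 0:
            raise ValidationError("OTU table contains no OTUs")
        if counts.shape[1] == 0:
            raise ValidationError("OTU table contains no samples")
        if counts.index.has_duplicates:
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate OTU ids: {dupes}")
        if counts.columns.has_duplicates:
            dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("OTU table contains non-numeric counts")
        if np.isnan(values.astype(float)).any():
            raise ValidationError("OTU table contains missing counts")
        if (values < 0).any():
            raise ValidationError("OTU table contains negative counts")
        if not np.allclose(values, np.round(values.astype(float))):
            raise ValidationError("OTU table contains non-integer counts")
        counts = counts.astype(np.int64)
        counts.index = counts.index.astype(str)
        counts.columns = counts.columns.astype(str)
        self.counts = counts

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_depths(self) -> pd.Series:
        """Total reads per sample."""
        return self.counts.sum(axis=0)

    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def drop_empty_otus(self) -> "OtuTable":
        """Return a copy without all-zero OTU rows (keeps >= 1 row)."""
        keep = self.counts.sum(axis=1) > 0
        if not keep.any():
            raise ValidationError("dropping empty OTUs would leave no OTUs")
        return OtuTable(self.counts.loc[keep])

    def select_samples(self, sample_ids: Iterable[str]) -> "OtuTable":
        return OtuTable(self.counts.loc[:, list(sample_ids)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.otu_ids == other.otu_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts.to_numpy(), other.counts.to_numpy())
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, m = self.shape
        return f"<OtuTable {n} OTUs x {m} samples, {self.total_reads()} reads>"


class SampleMetadata:
    """Per-sample annotations: density, replicate group, community, treatment.

    Backed by a DataFrame indexed by ``sample_id`` with columns
    ``density`` (16S copies/ml, >= 0; controls may be 0),
    ``replicate_group``, ``community_id``, ``treatment`` (``none`` or
    ``concentrated``) and ``is_control`` (bool).
    """

    REQUIRED = ("density", "replicate_group")

    def __init__(self, frame: pd.DataFrame):
        frame = pd.DataFrame(frame).copy()
        if "sample_id" in frame.columns:
            frame = frame.set_index("sample_id")
        frame.index = frame.index.astype(str)
        frame.index.name = "sample_id"
        if frame.index.has_duplicates:
            dupes = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids in metadata: {dupes}")
        for col in self.REQUIRED:
            if col not in frame.columns:
                raise ValidationError(f"metadata is missing required column {col!r}")
        frame["density"] = pd.to_numeric(frame["density"], errors="raise").astype(float)
        if frame["density"].isna().any() or (frame["density"] < 0).any():
            raise ValidationError("metadata densities must be >= 0 and non-missing")
        frame["replicate_group"] = frame["replicate_group"].astype(str)
        if "community_id" not in frame.columns:
            frame["community_id"] = ""
        frame["community_id"] = frame["community_id"].fillna("").astype(str)
        if "treatment" not in frame.columns:
            frame["treatment"] = "none"
        frame["treatment"] = frame["treatment"].fillna("none").astype(str)
        bad = set(frame["treatment"]) - set(TREATMENTS)
        if bad:
            raise ValidationError(f"unknown treatment values: {sorted(bad)}")
        if "is_control" not in frame.columns:
            frame["is_control"] = False
        frame["is_control"] = frame["is_control"].map(_as_bool)
        cols = ["density", "replicate_group", "community_id", "treatment", "is_control"]
        self.frame = frame[cols]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def density(self) -> pd.Series:
        return self.frame["density"]

    @property
    def is_control(self) -> pd.Series:
        return self.frame["is_control"]

    def replicate_groups(self, min_size: int = 2) -> dict[str, list[str]]:
        """Map replicate-group id -> sample ids, keeping groups of >= min_size."""
        groups: dict[str, list[str]] = {}
        for group, sub in self.frame.groupby("replicate_group", sort=True):
            if len(sub) >= min_size:
                groups[str(group)] = list(sub.index)
        return groups

    def aligned_to(self, table: OtuTable) -> "SampleMetadata":
        """Check 1:1 pairing with a table's samples and return matching rows."""
        missing = [s for s in table.sample_ids if s not in self.frame.index]
        if missing:
            raise ValidationError(f"samples without metadata: {missing}")
        return SampleMetadata(self.frame.loc[table.sample_ids].reset_index())

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<SampleMetadata {len(self)} samples>"


def _as_bool(value: object) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"true", "t", "1", "yes"}:
        return True
    if text in {"false", "f", "0", "no", "", "nan"}:
        return False
    raise ValidationError(f"cannot interpret {value!r} as a boolean flag")


@dataclass(frozen=True)
class Lineage:
    """Ordered rank-prefixed taxonomy labels, e.g. ``g__Burkholderia``.

    Ranks must appear in canonical kingdom-to-species order; gaps are
    allowed (an OTU may be labelled only to family, say).
    """

    labels: tuple[str, ...]

    def __post_init__(self):
        positions = []
        for label in self.labels:
            if len(label) < 3 or label[1:3] != "__" or label[0] not in RANKS:
                raise ValidationError(f"malformed lineage label {label!r}")
            positions.append(RANKS.index(label[0]))
        if positions != sorted(positions) or len(set(positions)) != len(positions):
            raise ValidationError(
                f"lineage ranks out of canonical order: {'; '.join(self.labels)}"
            )

    @classmethod
    def parse(cls, text: str, sep: str = ";") -> "Lineage":
        parts = [p.strip() for p in text.split(sep) if p.strip()]
        return cls(tuple(parts))

    def at_rank(self, rank: str) -> str | None:
        """The bare name at ``rank`` (single-letter code), or None."""
        for label in self.labels:
            if label[0] == rank:
                return label[3:]
        return None

    def deepest(self) -> str:
        return self.labels[-1]

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def __str__(self) -> str:
        return "; ".join(self.labels)


class TaxonomyMap:
    """Mapping of OTU id -> :class:`Lineage`."""

    def __init__(self, lineages: Mapping[str, Lineage]):
        self.lineages = {str(k): v for k, v in lineages.items()}

    @classmethod
    def from_strings(cls, strings: Mapping[str, str], sep: str = ";") -> "TaxonomyMap":
        return cls({otu: Lineage.parse(s, sep=sep) for otu, s in strings.items()})

    def __getitem__(self, otu_id: str) -> Lineage:
        return self.lineages[otu_id]

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.lineages

    def __len__(self) -> int:
        return len(self.lineages)

    def items(self):
        return self.lineages.items()

    def rank_of(self, otu_id: str, rank: str) -> str | None:
        if otu_id not in self.lineages:
            return None
        return self.lineages[otu_id].at_rank(rank)


@dataclass
class ExpectedComposition:
    """Known relative-abundance vector of one mock community.

    ``fractions`` maps a rank-prefixed taxon label (the deepest rank at
    which the member is defined, e.g. ``s__Pseudomonas aeruginosa``) to
    its expected fraction.  Fractions are strictly positive and sum to 1.
    """

    community_id: str
    fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.fractions = {str(k): float(v) for k, v in self.fractions.items()}
        if not self.fractions:
            raise ValidationError("expected composition has no taxa")
        if any(v <= 0 for v in self.fractions.values()):
            raise ValidationError("expected fractions must be > 0")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"expected fractions for {self.community_id} sum to {total}, not 1"
            )

    @property
    def taxa(self) -> list[str]:
        return list(self.fractions)

    def as_series(self) -> pd.Series:
        return pd.Series(self.fractions, name=self.community_id, dtype=float)
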