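"""Study-design primitives for a three-member bacterial community experiment.

The community members are abbreviated by single letters throughout:

* ``B`` — *Bacillus cereus*
* ``F`` — *Flavobacterium johnsoniae*
* ``K`` — *Pseudomonas koreensis*

A *condition* is the subset of members inoculated into a culture (``"B"``,
``"BF"``, ``"BFK"``, ...), or sterile media (``"media"``, the empty subset).
Cultures that contain *P. koreensis* come in two genotypes: wild type and a
koreenceine-null (Δkec) knockout in which the koreenceine biosynthetic gene
cluster is deleted.  The experiment runs two parallel *series* of all
conditions — one alongside wild-type K, one alongside the knockout — sharing a
single set of media blanks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import ParseError, ValidationError

SPECIES = ("B", "F", "K")

WILD_TYPE = "wild_type"
KEC_NULL = "kec_null"
NOT_APPLICABLE = "not_applicable"
GENOTYPES = (WILD_TYPE, KEC_NULL, NOT_APPLICABLE)

#: canonical ordering of the seven non-media conditions
CONDITION_ORDER = ("B", "F", "K", "BF", "BK", "FK", "BFK")

MEDIA_NAME = "media"

SERIES_WT = "wt"
SERIES_KEC = "kec"


def parse_condition_string(text: str, path=None, line=None) -> frozenset:
    """Parse a condition label like ``"KFB"`` (order-insensitive) or ``"media"``."""
    text = text.strip()
    if text.lower() == MEDIA_NAME:
        return frozenset()
    members = set()
    for ch in text:
        if ch not in SPECIES:
            raise ParseError(
                f"unknown species letter {ch!r} in condition {text!r}", path, line
            )
        members.add(ch)
    if not members:
        raise ParseError("empty condition string", path, line)
    return frozenset(members)


def condition_name(species: Iterable[str]) -> str:
    """Canonical name for a species subset (letters in B, F, K order)."""
    s = set(species)
    if not s:
        return MEDIA_NAME
    return "".join(letter for letter in SPECIES if letter in s)


@dataclass(frozen=True)
class Condition:
    """A culture condition: which members are present, and the K genotype.

    ``genotype`` is only meaningful when *P. koreensis* (K) is present; it must
    be ``not_applicable`` for media and for K-free conditions.
    """

    species: frozenset = field(default_factory=frozenset)
    genotype: str = NOT_APPLICABLE

    def __post_init__(self):
        unknown = set(self.species) - set(SPECIES)
        if unknown:
            raise ValidationError(f"unknown species {sorted(unknown)}")
        if self.genotype not in GENOTYPES:
            raise ValidationError(f"unknown genotype {self.genotype!r}")
        if "K" not in self.species and self.genotype != NOT_APPLICABLE:
            raise ValidationError(
                f"genotype {self.genotype!r} requires K in the condition "
                f"(got {self.name!r})"
            )

    @classmethod
    def from_string(cls, text: str, genotype: str = NOT_APPLICABLE) -> "Condition":
        return cls(parse_condition_string(text), genotype)

    @property
    def is_media(self) -> bool:
        return not self.species

    @property
    def name(self) -> str:
        return condition_name(self.species)

    @property
    def n_species(self) -> int:
        return len(self.species)


@dataclass(frozen=True)
class Sample:
    """One culture (or blank): id, condition, replicate number, series label."""

    sample_id: str
    condition: Condition
    replicate: int
    series: Optional[str] = None  # "wt" | "kec" | None for media blanks

    def __post_init__(self):
        if self.replicate < 1:
            raise ValidationError(
                f"replicate must be a positive integer (sample {self.sample_id})"
            )
        if self.condition.is_media and self.series is not None:
            raise ValidationError(
                f"media blank {self.sample_id} must not carry a series label"
            )


class StudyDesign:
    """Ordered collection of samples with lookup helpers.

    Sample ids are the join key across the count matrix, the molecular-feature
    table and the design; they must be unique.
    """

    def __init__(self, samples: Iterable[Sample]):
        self.samples = list(samples)
        seen = set()
        for s in self.samples:
            if s.sample_id in seen:
                raise ValidationError(f"duplicate sample id {s.sample_id!r}")
            seen.add(s.sample_id)
        self._by_id = {s.sample_id: s for s in self.samples}

    def __len__(self):
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def sample_ids(self):
        return [s.sample_id for s in self.samples]

    def condition_of(self, sample_id: str) -> Condition:
        try:
            return self._by_id[sample_id].condition
        except KeyError:
            raise ValidationError(f"unknown sample id {sample_id!r}") from None

    def sample(self, sample_id: str) -> Sample:
        try:
            return self._by_id[sample_id]
        except KeyError:
            raise ValidationError(f"unknown sample id {sample_id!r}") from None

    def media_samples(self):
        return [s for s in self.samples if s.condition.is_media]

    def non_media_samples(self, series: Optional[str] = None):
        out = [s for s in self.samples if not s.condition.is_media]
        if series is not None:
            out = [s for s in out if s.series == series]
        return out

    def series_labels(self):
        return sorted({s.series for s in self.samples if s.series is not None})

    def condition_names(self, series: Optional[str] = None):
        """Distinct non-media condition names, in canonical order."""
        names = {s.condition.name for s in self.non_media_samples(series)}
        ordered = [c for c in CONDITION_ORDER if c in names]
        ordered += sorted(names - set(CONDITION_ORDER))
        return ordered

    def replicates_of(self, condition_name_: str, series: Optional[str] = None):
        """Samples of one condition (optionally one series), in design order."""
        return [
            s
            for s in self.non_media_samples(series)
            if s.condition.name == condition_name_
        ]
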