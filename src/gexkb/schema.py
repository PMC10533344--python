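"""Annotation schema shared by every pipeline stage.

A gene expression-cancer association is described by four categorical
*aspects*:

``CGE``
    change of gene expression — ``up``, ``down`` or ``notinf`` (not
    informative / unstated).
``CCS``
    change of cancer status — ``progression``, ``regression`` or ``notinf``.
``GCI``
    gene-cancer interaction — ``causality``, ``correlation`` (alias
    ``observation``) or ``notinf``.
``GCC``
    gene-cancer context — a coarse utility filter: ``expression`` if the
    sentence is about a gene-expression-cancer association, ``other``
    otherwise.

Per-sentence evidence is a probability distribution over each aspect's
values (an :class:`AspectScoreVector`); manual annotations are exact
one-hot vectors.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import IO, Mapping, Optional, Union

import yaml

__all__ = [
    "CGE", "CCS", "GCI", "GCC",
    "ASPECTS", "RELATION_ASPECTS", "NEOPLASTIC_PROCESS",
    "SchemaError",
    "canonicalize_aspect_value", "validate_score_vector",
    "AspectScoreVector", "GeneEntity", "CancerEntity", "Mention",
    "EntityAnnotatedSentence", "RelationAnnotatedSentence", "Config",
]

CGE = "CGE"
CCS = "CCS"
GCI = "GCI"
GCC = "GCC"

#: Aspect name -> ordered tuple of canonical value labels.
ASPECTS: Mapping[str, tuple[str, ...]] = {
    CGE: ("up", "down", "notinf"),
    CCS: ("progression", "regression", "notinf"),
    GCI: ("causality", "correlation", "notinf"),
    GCC: ("expression", "other"),
}

#: Aspects that participate in facts; GCC is consumed by filtering only.
RELATION_ASPECTS: tuple[str, ...] = (CGE, CCS, GCI)

#: UMLS semantic-type code for "Neoplastic Process" — the disease gate.
NEOPLASTIC_PROCESS = "T191"

#: Accepted input synonyms, canonicalized on the way in.
_ALIASES: Mapping[str, Mapping[str, str]] = {
    GCI: {"observation": "correlation"},
}

DEFAULT_TOLERANCE = 1e-9


class SchemaError(ValueError):
    """Raised when a record violates the annotation schema."""


def canonicalize_aspect_value(aspect: str, raw_label: str) -> str:
    """Resolve ``raw_label`` to the canonical value label of ``aspect``.

    ``observation`` is accepted as an alias of the GCI value
    ``correlation``.  Canonicalization is idempotent.
    """
    if aspect not in ASPECTS:
        raise SchemaError(f"unknown aspect {aspect!r}")
    label = _ALIASES.get(aspect, {}).get(raw_label, raw_label)
    if label not in ASPECTS[aspect]:
        raise SchemaError(f"unknown value {raw_label!r} for aspect {aspect}")
    return label


@dataclass(frozen=True)
class AspectScoreVector:
    """Probability distribution over one aspect's values for one sentence."""

    aspect: str
    scores: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", dict(self.scores))

    # -- constructors ----------------------------------------------------

    @classmethod
    def one_hot(cls, aspect: str, value: str) -> "AspectScoreVector":
        value = canonicalize_aspect_value(aspect, value)
        return cls(aspect, {v: (1.0 if v == value else 0.0) for v in ASPECTS[aspect]})

    @classmethod
    def uniform(cls, aspect: str) -> "AspectScoreVector":
        values = ASPECTS[aspect]
        return cls(aspect, {v: 1.0 / len(values) for v in values})

    # -- queries ---------------------------------------------------------

    def argmax_set(self, tolerance: float = DEFAULT_TOLERANCE) -> frozenset[str]:
        """Values attaining the maximum score (more than one on ties)."""
        top = max(self.scores.values())
        return frozenset(v for v, s in self.scores.items() if top - s <= tolerance)

    def is_one_hot(self) -> bool:
        return all(s in (0.0, 1.0) for s in self.scores.values()) and \
            sum(self.scores.values()) == 1.0


def validate_score_vector(
    v: AspectScoreVector, tolerance: float = DEFAULT_TOLERANCE
) -> AspectScoreVector:
    """Check the distribution invariant and pass the vector through.

    Scores must cover every value of the aspect domain exactly, lie in
    [0, 1], and sum to 1 within ``tolerance``.
    """
    if v.aspect not in ASPECTS:
        raise SchemaError(f"unknown aspect {v.aspect!r}")
    domain = set(ASPECTS[v.aspect])
    got = set(v.scores)
    if got != domain:
        missing, extra = domain - got, got - domain
        raise SchemaError(
            f"{v.aspect} score vector keys mismatch: missing {sorted(missing)}, "
            f"unexpected {sorted(extra)}"
        )
    for value, s in v.scores.items():
        if not (0.0 <= s <= 1.0):
            raise SchemaError(f"{v.aspect} score for {value!r} outside [0,1]: {s}")
    total = sum(v.scores.values())
    if abs(total - 1.0) > tolerance:
        raise SchemaError(f"{v.aspect} scores sum to {total!r}, not 1")
    return v


@dataclass(frozen=True, order=True)
class GeneEntity:
    """A gene, identified by its NCBI Gene numeric id."""

    gene_id: int
    symbol: str = ""

    def __post_init__(self) -> None:
        if not (isinstance(self.gene_id, int) and self.gene_id > 0):
            raise SchemaError(f"gene_id must be a positive integer, got {self.gene_id!r}")


@dataclass(frozen=True, order=True)
class CancerEntity:
    """A cancer concept: UMLS CUI restricted to the neoplastic-process type."""

    cui: str
    preferred_name: str = ""
    semantic_type: str = NEOPLASTIC_PROCESS

    def __post_init__(self) -> None:
        c = self.cui
        if not (len(c) == 8 and c[0] == "C" and c[1:].isdigit()):
            raise SchemaError(f"malformed UMLS CUI {c!r} (expected C + 7 digits)")


@dataclass(frozen=True)
class Mention:
    """An entity occurrence: half-open character span within a text."""

    entity: Union[GeneEntity, CancerEntity]
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise SchemaError(f"invalid span [{self.start}, {self.end})")


@dataclass(frozen=True)
class EntityAnnotatedSentence:
    """One sentence carrying exactly one gene and one cancer mention.

    Spans are 0-based, half-open, in characters of ``text``, and must not
    cross each other.
    """

    sentence_id: str
    document_id: str
    text: str
    gene_mention: Mention
    cancer_mention: Mention

    def __post_init__(self) -> None:
        if not isinstance(self.gene_mention.entity, GeneEntity):
            raise SchemaError("gene_mention must carry a GeneEntity")
        if not isinstance(self.cancer_mention.entity, CancerEntity):
            raise SchemaError("cancer_mention must carry a CancerEntity")
        n = len(self.text)
        for m in (self.gene_mention, self.cancer_mention):
            if m.end > n:
                raise SchemaError(
                    f"mention span [{m.start}, {m.end}) outside sentence of length {n}"
                )
        g, c = self.gene_mention, self.cancer_mention
        if g.start < c.end and c.start < g.end:
            raise SchemaError("gene and cancer mention spans overlap")

    @property
    def gene(self) -> GeneEntity:
        return self.gene_mention.entity

    @property
    def cancer(self) -> CancerEntity:
        return self.cancer_mention.entity

    @property
    def pair_key(self) -> tuple[int, str]:
        return (self.gene.gene_id, self.cancer.cui)


@dataclass(frozen=True)
class RelationAnnotatedSentence:
    """An entity-annotated sentence plus one score vector per aspect."""

    sentence: EntityAnnotatedSentence
    cge: AspectScoreVector
    ccs: AspectScoreVector
    gci: AspectScoreVector
    gcc: AspectScoreVector
    provenance: str = "automatic"
    scorer_version: str = ""

    def __post_init__(self) -> None:
        expected = {CGE: self.cge, CCS: self.ccs, GCI: self.gci, GCC: self.gcc}
        for aspect, vec in expected.items():
            if vec.aspect != aspect:
                raise SchemaError(f"vector in {aspect} slot has aspect {vec.aspect!r}")
            validate_score_vector(vec)
        if self.provenance not in ("manual", "automatic"):
            raise SchemaError(f"unknown provenance {self.provenance!r}")
        if self.provenance == "manual":
            for vec in expected.values():
                if not vec.is_one_hot():
                    raise SchemaError(
                        f"manual annotation requires exact one-hot vectors; "
                        f"{vec.aspect} is {dict(vec.scores)}"
                    )

    def vector(self, aspect: str) -> AspectScoreVector:
        return {CGE: self.cge, CCS: self.ccs, GCI: self.gci, GCC: self.gcc}[aspect]

    @property
    def sentence_id(self) -> str:
        return self.sentence.sentence_id


@dataclass(frozen=True)
class Config:
    """System thresholds and numeric settings.

    alpha
        sufficiency threshold: a fact is unreliable if the likelihood of a
        not-informative CCS or GCI value strictly exceeds it.
    beta
        consistency margin: the top gene-class likelihood must exceed the
        runner-up by more than beta.
    k
        active-learning batch size, counted in sentences.
    log_base
        entropy logarithm base; ``None`` means the natural logarithm.
        The ranking induced by the reliability score is base-invariant.
    """

    alpha: float = 0.7
    beta: float = 0.4
    k: int = 250
    log_base: Optional[float] = None
    tolerance: float = DEFAULT_TOLERANCE
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise SchemaError(f"alpha outside [0,1]: {self.alpha}")
        if not (0.0 <= self.beta <= 1.0):
            raise SchemaError(f"beta outside [0,1]: {self.beta}")
        if not (isinstance(self.k, int) and self.k > 0):
            raise SchemaError(f"k must be a positive integer, got {self.k!r}")
        if self.log_base is not None and (self.log_base <= 0 or self.log_base == 1):
            raise SchemaError(f"invalid log base {self.log_base!r}")
        if self.tolerance <= 0:
            raise SchemaError("tolerance must be positive")

    @classmethod
    def from_yaml(cls, source: Union[str, IO[str]]) -> "Config":
        data = yaml.safe_load(source.read() if hasattr(source, "read") else source)
        if data is None:
            data = {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    def log(self, x: float) -> float:
        return math.log(x) if self.log_base is None else math.log(x, self.log_base)
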