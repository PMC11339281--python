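"""Gene-set containers and GMT I/O for the regulated-cell-death signatures.

Twelve regulated cell death (RCD) paradigms are tested against every NK
cluster.  Because the six death states reported downstream merge the two
apoptotic and the two necrotic paradigms, a fixed aggregation map and a fixed
canonical paradigm order (used for deterministic tie-breaking) live here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: Canonical order of the twelve RCD paradigms (Cell Death Nomenclature
#: Committee naming).  The order is fixed so that downstream ties are broken
#: deterministically.
CANONICAL_PARADIGMS: tuple[str, ...] = (
    "intrinsic_apoptosis",
    "extrinsic_apoptosis",
    "mpt_driven_necrosis",
    "necroptosis",
    "ferroptosis",
    "pyroptosis",
    "parthanatos",
    "entotic_cell_death",
    "netotic_cell_death",
    "lysosome_dependent_cell_death",
    "autophagy_dependent_cell_death",
    "immunogenic_cell_death",
)

#: Paradigm -> reported death state.  Intrinsic + extrinsic apoptosis are
#: reported together as "apoptosis"; MPT-driven necrosis + necroptosis as
#: "necrotic".  The remaining paradigms report under their own (shortened)
#: names.
STATE_AGGREGATION: dict[str, str] = {
    "intrinsic_apoptosis": "apoptosis",
    "extrinsic_apoptosis": "apoptosis",
    "mpt_driven_necrosis": "necrotic",
    "necroptosis": "necrotic",
    "ferroptosis": "ferroptosis",
    "pyroptosis": "pyroptosis",
    "parthanatos": "parthanatos",
    "entotic_cell_death": "entotic",
    "netotic_cell_death": "netotic",
    "lysosome_dependent_cell_death": "lysosome_dependent",
    "autophagy_dependent_cell_death": "autophagy",
    "immunogenic_cell_death": "immunogenic",
}

#: The six death states the composition tables report, plus healthy.
REPORTED_STATES: tuple[str, ...] = (
    "apoptosis",
    "pyroptosis",
    "necrotic",
    "ferroptosis",
    "autophagy",
    "immunogenic",
)

HEALTHY_LABEL = "healthy"


class GeneSetError(ValueError):
    """Malformed gene set or GMT file."""


@dataclass
class GeneSet:
    """A named gene set with a free-text source annotation."""

    name: str
    genes: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise GeneSetError("gene set needs a non-empty name")
        genes = tuple(g.upper() for g in self.genes)
        if not genes:
            raise GeneSetError(f"gene set {self.name!r} is empty")
        seen: set[str] = set()
        deduped = []
        for g in genes:
            if g in seen:
                continue
            seen.add(g)
            deduped.append(g)
        if len(deduped) < len(genes):
            warnings.warn(f"gene set {self.name!r}: duplicated genes removed")
        object.__setattr__(self, "genes", tuple(deduped))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass
class GeneSetCollection:
    """Ordered collection of uniquely named gene sets."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise GeneSetError(f"duplicate set names: {dupes}")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def validate_paradigms(self, override: Sequence[str] | None = None) -> None:
        """Refuse classification unless the collection names exactly the
        twelve canonical paradigms (or a user-supplied override list)."""
        expected = set(override) if override is not None else set(CANONICAL_PARADIGMS)
        got = set(self.names)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise GeneSetError(
                "collection does not name the expected paradigms; "
                f"missing={missing} extra={extra}"
            )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated
    ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GeneSetError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected at least 3 (name, description, >=1 gene)"
                )
            name, source, *genes = fields
            genes = [g for g in genes if g]
            sets.append(GeneSet(name=name, genes=tuple(genes), source=source))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection | Iterable[GeneSet], path: str | Path) -> Path:
    """Write a GMT file.  Empty sets are rejected (the GeneSet constructor
    refuses them, so this is a belt-and-braces check for raw tuples)."""
    path = Path(path)
    sets = list(collection)
    for s in sets:
        if len(s.genes) == 0:
            raise GeneSetError(f"refusing to write empty gene set {s.name!r}")
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.source or "na", *s.genes]) + "\n")
    return path


def restrict_to_universe(
    collection: GeneSetCollection,
    universe: Iterable[str],
    min_size: int = 5,
) -> GeneSetCollection:
    """Intersect every set with the measured gene universe; sets falling
    below ``min_size`` are dropped with a warning."""
    universe = {g.upper() for g in universe}
    if not universe:
        raise GeneSetError("gene universe is empty")
    kept: list[GeneSet] = []
    for s in collection:
        genes = tuple(g for g in s.genes if g in universe)
        if len(genes) < min_size:
            warnings.warn(
                f"gene set {s.name!r} has only {len(genes)} genes in the "
                f"universe (<{min_size}); dropped"
            )
            continue
        kept.append(GeneSet(name=s.name, genes=genes, source=s.source))
    if not kept:
        raise GeneSetError("no gene set survives restriction to the universe")
    return GeneSetCollection(sets=kept)


def packaged_death_paradigms() -> GeneSetCollection:
    """The packaged example GMT of the twelve paradigms.

    These memberships are synthetic placeholders (the literature signatures
    live in curated databases); users reproducing published numbers must
    supply their own GMT.
    """
    ref = resources.files("nkfate") / "data" / "death_paradigms_synthetic.gmt"
    with resources.as_file(ref) as p:
        return read_gmt(p)


def aggregate_state(paradigm: str) -> str:
    """Map a paradigm label (or 'healthy') to its reported death state."""
    if paradigm == HEALTHY_LABEL:
        return HEALTHY_LABEL
    try:
        return STATE_AGGREGATION[paradigm]
    except KeyError:
        raise GeneSetError(f"unknown paradigm {paradigm!r}") from None
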