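"""Culture conditions for a small model community.

A :class:`Condition` is the key of the whole experimental design: which
species were inoculated together (a nonempty membership set such as
``{"B", "F", "P"}``), the genotype of the antibiotic producer (wild type or
the biosynthetic-cluster deletion ``dkec``), and the producer's inoculum
level (``standard`` or ``low``).  Canonical names concatenate the sorted
member labels ("B", "BF", "BFP", ...) with optional ``_dkec`` / ``_PLI``
suffixes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DEFAULT_ROSTER = ("B", "F", "P")

#: species whose genotype / inoculum modifiers are meaningful
PRODUCER = "P"

GENOTYPES = ("WT", "dkec")
INOCULA = ("standard", "low")


@dataclass(frozen=True, order=True)
class Condition:
    """A culture state: membership set + genotype + inoculum level."""

    # the canonical name encodes members, genotype and inoculum exactly, so
    # equality/ordering/hash on it matches field-wise equality
    sort_index: str = field(init=False, repr=False)
    members: frozenset = field(compare=False)
    genotype: str = field(default="WT", compare=False)
    inoculum: str = field(default="standard", compare=False)

    def __init__(self, members, genotype: str = "WT", inoculum: str = "standard"):
        members = frozenset(members)
        if not members:
            raise ValueError("Condition must have at least one member species")
        for m in members:
            if not (isinstance(m, str) and m):
                raise ValueError(f"invalid species label: {m!r}")
        if genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
        if inoculum not in INOCULA:
            raise ValueError(f"unknown inoculum {inoculum!r}; expected one of {INOCULA}")
        if genotype == "dkec" and PRODUCER not in members:
            raise ValueError("genotype 'dkec' requires the producer species "
                             f"{PRODUCER!r} among the members")
        if inoculum == "low" and PRODUCER not in members:
            raise ValueError("inoculum 'low' is only meaningful when the producer "
                             f"{PRODUCER!r} is present")
        object.__setattr__(self, "members", members)
        object.__setattr__(self, "genotype", genotype)
        object.__setattr__(self, "inoculum", inoculum)
        object.__setattr__(self, "sort_index", self._name())

    def _name(self) -> str:
        name = "".join(sorted(self.members))
        if self.genotype == "dkec":
            name += "_dkec"
        if self.inoculum == "low":
            name += "_PLI"
        return name

    @property
    def name(self) -> str:
        """Canonical condition name, e.g. ``"BFP"`` or ``"FP_PLI"``."""
        return self.sort_index

    @classmethod
    def from_name(cls, name: str) -> "Condition":
        """Parse a canonical condition name back into a :class:`Condition`."""
        genotype, inoculum = "WT", "standard"
        base = name
        if base.endswith("_PLI"):
            inoculum = "low"
            base = base[: -len("_PLI")]
        if base.endswith("_dkec"):
            genotype = "dkec"
            base = base[: -len("_dkec")]
        if not base:
            raise ValueError(f"empty membership in condition name {name!r}")
        return cls(frozenset(base), genotype=genotype, inoculum=inoculum)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name

    def validate_roster(self, roster) -> None:
        extra = self.members - set(roster)
        if extra:
            raise ValueError(
                f"condition {self.name!r} contains species {sorted(extra)} "
                f"not in the roster {sorted(roster)}")


def core_conditions(species: str, roster=DEFAULT_ROSTER):
    """The four wild-type conditions a focal species is filtered over.

    For focal species X with partners Y, Z these are X, XY, XZ and XYZ
    (monoculture, two pairwise cocultures, full community).
    """
    roster = tuple(roster)
    if species not in roster:
        raise ValueError(f"{species!r} not in roster {roster}")
    partners = [s for s in roster if s != species]
    conds = [Condition({species})]
    for p in partners:
        conds.append(Condition({species, p}))
    conds.append(Condition(roster))
    return conds
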