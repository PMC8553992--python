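"""Region sets: ordered, unique brain-region labels.

The region order is fixed at construction and defines row/column order for
every downstream matrix (correlation, distance) and node order for graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class RegionSet:
    """Ordered collection of unique, non-empty region labels."""

    names: tuple[str, ...] = field(default_factory=tuple)

    def __init__(self, names) -> None:
        names = tuple(str(n) for n in names)
        if not names:
            raise ValueError("RegionSet requires at least one region label")
        if any(not n for n in names):
            raise ValueError("region labels must be non-empty")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate region labels: {dupes}")
        object.__setattr__(self, "names", names)

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def index(self, name: str) -> int:
        return self.names.index(name)


#: The 13 regions of the social decision-making network (SDMN): the social
#: behavioral network plus the mesolimbic reward system. Abbreviations are
#: the field-standard ones (AH = anterior hypothalamus, BLA = basolateral
#: amygdala, BNST = bed nucleus of the stria terminalis, HIP = hippocampus,
#: LS = lateral septum, MeA = medial amygdala, mPOA = medial preoptic area,
#: NAcc = nucleus accumbens, PAG = periaqueductal gray, CP = caudate putamen,
#: VMH = ventromedial hypothalamus, VP = ventral pallidum, VTA = ventral
#: tegmental area).
SDMN_REGIONS = RegionSet(
    [
        "AH",
        "BLA",
        "BNST",
        "HIP",
        "LS",
        "MeA",
        "mPOA",
        "NAcc",
        "PAG",
        "CP",
        "VMH",
        "VP",
        "VTA",
    ]
)
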