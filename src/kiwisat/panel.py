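"""Marker panel definitions.

A panel is an ordered list of microsatellite loci, each with a repeat unit
(allele sizes are integer multiples of it apart), a fragment-size range, and
a flag marking the single sex-linked locus. The default panel mirrors a
kiwi (*Apteryx* spp.) monitoring panel of 22 autosomal loci plus the
EST-derived sex-linked locus Z37B.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Locus:
    """One microsatellite locus.

    Parameters
    ----------
    name : str
        Unique locus identifier.
    repeat_unit : int
        Repeat-motif length in bp; allele sizes differ by multiples of it.
    size_range : tuple[int, int]
        Inclusive (min, max) fragment size in bp.
    sex_linked : bool
        True for the single ZW sex-determination locus.
    """

    name: str
    repeat_unit: int
    size_range: tuple[int, int]
    sex_linked: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.size_range
        if lo <= 0 or hi <= 0 or lo >= hi:
            raise ValueError(
                f"locus {self.name}: size range must be positive with min < max, "
                f"got {self.size_range}"
            )
        if self.repeat_unit < 1:
            raise ValueError(f"locus {self.name}: repeat unit must be >= 1")

    def ladder(self) -> list[int]:
        """All allele sizes the locus admits (min to max by repeat unit)."""
        lo, hi = self.size_range
        return list(range(lo, hi + 1, self.repeat_unit))


@dataclass(frozen=True)
class PanelDefinition:
    """Ordered collection of loci with exactly one sex-linked locus."""

    loci: tuple[Locus, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [loc.name for loc in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("locus names must be unique")
        n_sex = sum(loc.sex_linked for loc in self.loci)
        if n_sex != 1:
            raise ValueError(f"exactly one sex-linked locus required, found {n_sex}")

    @property
    def locus_names(self) -> list[str]:
        return [loc.name for loc in self.loci]

    @property
    def autosomal(self) -> list[Locus]:
        return [loc for loc in self.loci if not loc.sex_linked]

    @property
    def sex_locus(self) -> Locus:
        return next(loc for loc in self.loci if loc.sex_linked)

    def __getitem__(self, name: str) -> Locus:
        for loc in self.loci:
            if loc.name == name:
                return loc
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.loci)


def default_kiwi_panel() -> PanelDefinition:
    """The 23-locus kiwi panel: 22 autosomal microsatellites + Z37B.

    Amplicon sizes span roughly 74-357 bp across the panel. Repeat units and
    ranges here are stylized per-locus ladders adequate for simulation; the
    sex locus Z37B carries the 92 bp W fragment and species-specific Z
    fragments between 94 and 100 bp.
    """
    autosomal = [
        ("KMS1", 2, (130, 170)),
        ("KMS2", 2, (100, 140)),
        ("KMS3", 4, (150, 210)),
        ("KMS7R", 2, (74, 110)),
        ("KMS10", 2, (200, 240)),
        ("KMS12", 4, (250, 310)),
        ("KMS14B", 2, (120, 160)),
        ("KMS16A", 2, (140, 180)),
        ("KMS18", 2, (90, 130)),
        ("KMS21", 4, (180, 240)),
        ("KMS24", 2, (160, 200)),
        ("KMS30", 2, (110, 150)),
        ("Aptowe5", 2, (210, 250)),
        ("Aptowe11", 4, (260, 320)),
        ("Aptowe16", 2, (150, 190)),
        ("Aptowe28", 2, (100, 140)),
        ("Aptowe29", 2, (170, 210)),
        ("Apt35", 2, (230, 270)),
        ("Apt49", 4, (300, 357)),
        ("Apt59", 2, (120, 160)),
        ("Apt68", 2, (190, 230)),
        ("Apt77", 2, (140, 180)),
    ]
    loci = [Locus(n, u, r) for n, u, r in autosomal]
    loci.append(Locus("Z37B", 2, (92, 100), sex_linked=True))
    return PanelDefinition(tuple(loci))
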