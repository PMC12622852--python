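"""Toy genome model: chromosomes, centromeres and arm coordinates.

All internal coordinates are 0-based half-open. The default genome is a
desk-scale stand-in (22 autosomes of 100 Mb, centromere at 40%); real-build
coordinates can be supplied through the same config mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

MB = 1_000_000

DEFAULT_GENOME_CONFIG = {
    "n_chromosomes": 22,
    "chromosome_length": 100 * MB,
    "centromere_fraction": 0.4,
}


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    centromere: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.name}: chromosome length must be > 0")
        if not 0 < self.centromere < self.length:
            raise ValueError(
                f"{self.name}: centromere {self.centromere} outside (0, {self.length})"
            )


@dataclass(frozen=True)
class Arm:
    """One chromosome arm as a half-open interval [start, end)."""

    chrom: str
    arm: str  # "p" or "q"
    start: int
    end: int

    @property
    def name(self) -> str:
        return f"{self.chrom}{self.arm}"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomeModel:
    """Spatial frame for all scar features: chromosomes split into p/q arms."""

    chromosomes: tuple[Chromosome, ...]
    arms: tuple[Arm, ...] = field(init=False)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        arms = []
        for c in self.chromosomes:
            arms.append(Arm(c.name, "p", 0, c.centromere))
            arms.append(Arm(c.name, "q", c.centromere, c.length))
        object.__setattr__(self, "arms", tuple(arms))

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    @property
    def chrom_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"unknown chromosome {name!r}")

    def arms_of(self, chrom: str) -> list[Arm]:
        return [a for a in self.arms if a.chrom == chrom]


def build_genome(config: dict | None = None) -> GenomeModel:
    """Build a :class:`GenomeModel` from a config dict.

    Two config dialects are accepted:

    * uniform: ``{"n_chromosomes": 22, "chromosome_length": 100e6,
      "centromere_fraction": 0.4}`` (any subset; defaults fill the rest);
    * explicit: ``{"chromosomes": [{"name": ..., "length": ...,
      "centromere": ...}, ...]}`` for real-build coordinates.

    Raises ``ValueError`` for non-positive lengths or a centromere fraction
    outside (0, 1).
    """
    if config is None:
        config = {}
    if "chromosomes" in config:
        chroms = tuple(
            Chromosome(str(c["name"]), int(c["length"]), int(c["centromere"]))
            for c in config["chromosomes"]
        )
        return GenomeModel(chroms)
    cfg = dict(DEFAULT_GENOME_CONFIG)
    cfg.update(config)
    n = int(cfg["n_chromosomes"])
    length = int(cfg["chromosome_length"])
    frac = float(cfg["centromere_fraction"])
    if n <= 0:
        raise ValueError("n_chromosomes must be > 0")
    if length <= 0:
        raise ValueError("chromosome_length must be > 0")
    if not 0 < frac < 1:
        raise ValueError(f"centromere_fraction {frac} outside (0, 1)")
    centromere = int(round(length * frac))
    chroms = tuple(
        Chromosome(f"chr{i + 1}", length, centromere) for i in range(n)
    )
    return GenomeModel(chroms)
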