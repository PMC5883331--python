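"""Gene sets: GMT I/O and the packaged HSE (human supragranular enriched) list.

The HSE set comprises 19 genes preferentially expressed in supragranular
layers (II/III) of human cortex, where most cortico-cortical projections
originate.  It ships as a GMT fixture so the coupling analysis can score it
like any other gene set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty collection of unique gene symbols."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate symbols")

    def __len__(self) -> int:
        return len(self.genes)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, symbols...)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets.append(GeneSet(fields[0], tuple(fields[2:]), fields[1]))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def hse_gene_set() -> GeneSet:
    """The packaged 19-gene HSE set."""
    with resources.as_file(
        resources.files("transcortex.data").joinpath("hse.gmt")
    ) as p:
        (hse,) = read_gmt(p)
    return hse
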