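"""Rule-based presence calling of respiratory complexes and marker genes.

A genome is called positive for a bioenergetic complex when its annotation
table contains at least ``min_present`` DISTINCT countable subunit families
of that complex — multiple genes in one family count once, and synteny is
not required (the decision rules are pure counts, and assembly
fragmentation breaks gene order in MAGs anyway). The shipped definitions:

* cNDH — canonical proton-pumping NADH:ubiquinone oxidoreductase, 14
  nuoA-N families, called on >= 6 of the 12 nuoA-L families (nuoM/nuoN are
  frequently encoded elsewhere on the chromosome and are not counted);
* nNDH — noncanonical NDH lacking the nuoD-F NADH-oxidising module, 8
  nuoABCGHIJK families in their own namespace, called on >= 5;
* NQR — Na+-translocating NADH:quinone oxidoreductase, 6 families,
  called on >= 3.

Single-gene markers (photolyase, proteorhodopsin, NarG, NarH, NuoH, NqrA)
are present iff their family id is annotated at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .io_formats import AnnotationTable


@dataclass(frozen=True)
class ComplexDefinition:
    """A named complex: its families, the countable subset and the threshold."""

    name: str
    all_families: tuple[str, ...]
    countable_families: tuple[str, ...]
    min_present: int

    def __post_init__(self) -> None:
        if not set(self.countable_families) <= set(self.all_families):
            raise ValueError(f"{self.name}: countable_families not a subset of all_families")
        if not (1 <= self.min_present <= len(self.countable_families)):
            raise ValueError(f"{self.name}: min_present out of range")


@dataclass(frozen=True)
class ComplexCall:
    genome_id: str
    complex_name: str
    n_subunits_found: int
    present: bool


def load_definitions(path: str | Path | None = None) -> dict[str, ComplexDefinition]:
    """Load complex definitions from YAML (the shipped file by default)."""
    if path is None:
        text = resources.files("streamline_scan.data").joinpath(
            "complex_definitions.yaml"
        ).read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    out = {}
    for name, spec in raw["complexes"].items():
        out[name] = ComplexDefinition(
            name=name,
            all_families=tuple(spec["all_families"]),
            countable_families=tuple(spec["countable_families"]),
            min_present=int(spec["min_present"]),
        )
    return out


def load_marker_panel(path: str | Path | None = None) -> dict[str, str]:
    """Marker name -> family id panel from the definitions YAML."""
    if path is None:
        text = resources.files("streamline_scan.data").joinpath(
            "complex_definitions.yaml"
        ).read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    return dict(yaml.safe_load(text)["markers"])


DEFAULT_DEFINITIONS = load_definitions()
DEFAULT_MARKER_PANEL = load_marker_panel()


def call_complex(
    table: AnnotationTable, genome_id: str, definition: ComplexDefinition
) -> ComplexCall:
    """Call one complex in one genome by distinct countable-family count."""
    if genome_id not in table:
        raise KeyError(f"genome {genome_id!r} not in annotation table")
    found = table.families(genome_id) & set(definition.countable_families)
    n = len(found)
    return ComplexCall(genome_id, definition.name, n, n >= definition.min_present)


def call_all(
    table: AnnotationTable,
    genomes: Sequence[str] | None = None,
    definitions: Mapping[str, ComplexDefinition] | None = None,
) -> list[ComplexCall]:
    """One call per (genome, complex), genomes then complexes in given order."""
    if genomes is None:
        genomes = table.genomes
    if definitions is None:
        definitions = DEFAULT_DEFINITIONS
    return [
        call_complex(table, g, d) for g in genomes for d in definitions.values()
    ]


def marker_presence(
    table: AnnotationTable,
    genomes: Sequence[str] | None = None,
    panel: Mapping[str, str] | None = None,
) -> dict[str, dict[str, bool]]:
    """Genome x marker boolean presence: true iff the family id is annotated."""
    if genomes is None:
        genomes = table.genomes
    if panel is None:
        panel = DEFAULT_MARKER_PANEL
    return {
        g: {marker: fam in table.families(g) for marker, fam in panel.items()}
        for g in genomes
    }
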