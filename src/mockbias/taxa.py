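"""Per-taxon metadata: 16S rRNA gene copy number, genome size, Gram status.

Copy number inflates amplicon read counts proportionally (a genome with seven
16S operons contributes seven templates per cell) and genome size dilutes the
per-nanogram template density of a taxon in a DNA mixture; both are needed to
convert read counts into cell- or DNA-proportion estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import SchemaError

REQUIRED_COLUMNS = ("name", "copy_number", "genome_size", "gram")


@dataclass(frozen=True)
class TaxonMeta:
    """Metadata for one bacterial strain.

    Parameters
    ----------
    name : str
        Taxon label, matched exactly (case-sensitive) across all tables.
    copy_number : int
        16S rRNA gene copies per genome; must be >= 1.
    genome_size : float
        Genome size in megabases; must be > 0.
    gram : str
        Gram stain status, "+" or "-".
    """

    name: str
    copy_number: int
    genome_size: float
    gram: str

    def __post_init__(self) -> None:
        if not self.name:
            raise SchemaError("taxon name must be non-empty")
        if int(self.copy_number) < 1:
            raise SchemaError(f"{self.name}: copy_number must be >= 1, got {self.copy_number}")
        if not self.genome_size > 0:
            raise SchemaError(f"{self.name}: genome_size must be > 0, got {self.genome_size}")
        if self.gram not in ("+", "-"):
            raise SchemaError(f"{self.name}: gram must be '+' or '-', got {self.gram!r}")


def taxa_frame(taxa: list[TaxonMeta]) -> pd.DataFrame:
    """Return the metadata as a DataFrame indexed by taxon name."""
    return pd.DataFrame(
        {
            "copy_number": [t.copy_number for t in taxa],
            "genome_size": [t.genome_size for t in taxa],
            "gram": [t.gram for t in taxa],
        },
        index=pd.Index([t.name for t in taxa], name="name"),
    )


def read_taxa(path: str | Path) -> list[TaxonMeta]:
    """Read a taxon metadata CSV with columns name, copy_number, genome_size, gram.

    Raises
    ------
    SchemaError
        If the file is empty, a required column is missing, or a value is
        out of range (copy_number < 1, genome_size <= 0, bad gram label).
    """
    try:
        frame = pd.read_csv(path, dtype={"name": str, "gram": str})
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty taxa file") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if len(frame) == 0:
        raise SchemaError(f"{path}: no taxa rows")
    taxa = []
    for _, row in frame.iterrows():
        cn = row["copy_number"]
        if float(cn) != int(cn):
            raise SchemaError(f"{row['name']}: copy_number must be an integer, got {cn}")
        taxa.append(
            TaxonMeta(
                name=str(row["name"]),
                copy_number=int(cn),
                genome_size=float(row["genome_size"]),
                gram=str(row["gram"]).strip(),
            )
        )
    names = [t.name for t in taxa]
    if len(set(names)) != len(names):
        raise SchemaError(f"{path}: duplicate taxon names")
    return taxa


def write_taxa(taxa: list[TaxonMeta], path: str | Path) -> None:
    frame = taxa_frame(taxa).reset_index()
    frame.to_csv(path, index=False)


def vaginal_panel() -> list[TaxonMeta]:
    """The seven-strain vaginally-relevant panel shipped with the package.

    Copy numbers and genome sizes (Mb) were estimated from NCBI genome
    annotations for the sequenced strains.
    """
    with resources.as_file(resources.files("mockbias.data") / "vaginal_panel.csv") as p:
        return read_taxa(p)
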