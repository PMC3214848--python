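"""SNP panel definitions.

A panel is an ordered list of biallelic autosomal markers, each with a
designated *risk allele* (the allele associated with the disease) and its
population frequency. Panel order is significant: it defines the genotype
column order in PED files and the position of each marker in per-individual
risk-allele count vectors.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import pandas as pd

__all__ = ["SNPDef", "SNPPanel", "read_panel", "load_default_panel"]

_NUCLEOTIDES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class SNPDef:
    """One biallelic marker with its risk allele and population frequency."""

    snp_id: str
    gene: str
    risk_allele: str
    other_allele: str
    risk_freq: float

    def __post_init__(self) -> None:
        if self.risk_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: risk and other allele must differ")
        for a in (self.risk_allele, self.other_allele):
            if a not in _NUCLEOTIDES:
                raise ValueError(f"{self.snp_id}: allele {a!r} is not a nucleotide")
        if not 0.0 <= self.risk_freq <= 1.0:
            raise ValueError(f"{self.snp_id}: risk_freq {self.risk_freq} outside [0, 1]")


class SNPPanel:
    """Ordered collection of :class:`SNPDef`, unique by snp_id."""

    def __init__(self, snps: list[SNPDef]):
        ids = [s.snp_id for s in snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp_id in panel")
        self.snps: tuple[SNPDef, ...] = tuple(snps)
        self._index: dict[str, int] = {s.snp_id: i for i, s in enumerate(self.snps)}

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self):
        return iter(self.snps)

    def __getitem__(self, key: int | str) -> SNPDef:
        if isinstance(key, str):
            return self.snps[self._index[key]]
        return self.snps[key]

    def __eq__(self, other) -> bool:
        return isinstance(other, SNPPanel) and self.snps == other.snps

    def index(self, snp_id: str) -> int:
        """Position of a marker in the panel (raises KeyError if absent)."""
        return self._index[snp_id]

    def indices(self, snp_ids) -> list[int]:
        return [self._index[s] for s in snp_ids]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": [s.snp_id for s in self.snps],
                "gene": [s.gene for s in self.snps],
                "risk_allele": [s.risk_allele for s in self.snps],
                "other_allele": [s.other_allele for s in self.snps],
                "risk_freq": [s.risk_freq for s in self.snps],
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_panel(path) -> SNPPanel:
    """Read a panel file: tab/whitespace-delimited with columns
    snp_id, gene, risk_allele, other_allele, risk_freq."""
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    required = {"snp_id", "gene", "risk_allele", "other_allele", "risk_freq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel file missing columns: {sorted(missing)}")
    snps = [
        SNPDef(
            snp_id=str(r.snp_id),
            gene=str(r.gene),
            risk_allele=str(r.risk_allele),
            other_allele=str(r.other_allele),
            risk_freq=float(r.risk_freq),
        )
        for r in df.itertuples()
    ]
    return SNPPanel(snps)


def load_default_panel() -> SNPPanel:
    """The packaged ten-gene autism susceptibility panel with exploratory-sample
    risk-allele frequencies."""
    ref = importlib.resources.files("sibscore.data").joinpath("panel.tsv")
    with importlib.resources.as_file(ref) as path:
        return read_panel(path)
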