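"""Containers for two-condition omics measurements.

All records compare a *perturbed* condition against a *reference* condition
(e.g. stationary vs exponential phase, sand vs liquid).  Gene records carry
the log2 fold-change and false-discovery rate from an upstream differential
expression analysis; metabolite records carry extracellular-abundance ratios
with a significance flag.  This module only stores, filters and (de)serializes
them — fitting the statistics from raw counts or spectra is upstream of this
package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

DEFAULT_FDR_CUTOFF = 0.05
DEFAULT_FOLD_THRESHOLD = 2.0  # theta; a gene is DE when |log2FC| >= log2(theta)


@dataclass
class GeneRecord:
    gene_id: str
    log2_fold_change: float
    fdr: float

    def __post_init__(self):
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"FDR for {self.gene_id!r} outside [0,1]: {self.fdr}")

    @property
    def ratio(self) -> float:
        """Perturbed/reference expression ratio (always > 0)."""
        return 2.0 ** self.log2_fold_change


@dataclass
class MetaboliteRecord:
    metabolite_id: str
    ratio: float  # perturbed/reference abundance
    significant: bool = True

    def __post_init__(self):
        if self.ratio <= 0:
            raise ValueError(
                f"abundance ratio for {self.metabolite_id!r} must be > 0"
            )


@dataclass
class OmicsData:
    """Per-gene and per-metabolite fold-change records for a condition pair."""

    gene_records: dict[str, GeneRecord] = field(default_factory=dict)
    metabolite_records: dict[str, MetaboliteRecord] = field(default_factory=dict)

    def significant_genes(
        self,
        fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
        fdr_cutoff: float = DEFAULT_FDR_CUTOFF,
    ) -> dict[str, GeneRecord]:
        """Genes passing FDR < cutoff and |log2FC| >= log2(threshold)."""
        log2_min = math.log2(fold_threshold)
        return {
            gid: rec
            for gid, rec in self.gene_records.items()
            if rec.fdr < fdr_cutoff and abs(rec.log2_fold_change) >= log2_min
        }

    def significant_metabolites(self) -> dict[str, MetaboliteRecord]:
        return {
            mid: rec for mid, rec in self.metabolite_records.items() if rec.significant
        }

    def inverted(self) -> "OmicsData":
        """Swap reference and perturbed roles (all ratios inverted)."""
        return OmicsData(
            gene_records={
                gid: GeneRecord(gid, -rec.log2_fold_change, rec.fdr)
                for gid, rec in self.gene_records.items()
            },
            metabolite_records={
                mid: MetaboliteRecord(mid, 1.0 / rec.ratio, rec.significant)
                for mid, rec in self.metabolite_records.items()
            },
        )


def load_gene_table(path) -> dict[str, GeneRecord]:
    """TSV with columns gene_id, log2fc, fdr."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return {
        str(row["gene_id"]): GeneRecord(
            str(row["gene_id"]), float(row["log2fc"]), float(row["fdr"])
        )
        for _, row in df.iterrows()
    }


def load_metabolite_table(path) -> dict[str, MetaboliteRecord]:
    """TSV with columns metabolite_id, ratio, significant."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return {
        str(row["metabolite_id"]): MetaboliteRecord(
            str(row["metabolite_id"]),
            float(row["ratio"]),
            bool(row["significant"]) if "significant" in df.columns else True,
        )
        for _, row in df.iterrows()
    }


def load_omics(genes_path=None, metabolites_path=None) -> OmicsData:
    data = OmicsData()
    if genes_path is not None:
        data.gene_records = load_gene_table(genes_path)
    if metabolites_path is not None:
        data.metabolite_records = load_metabolite_table(metabolites_path)
    return data


def write_omics(data: OmicsData, genes_path=None, metabolites_path=None) -> None:
    import pandas as pd

    if genes_path is not None:
        pd.DataFrame(
            [
                {"gene_id": gid, "log2fc": r.log2_fold_change, "fdr": r.fdr}
                for gid, r in data.gene_records.items()
            ]
        ).to_csv(Path(genes_path), sep="\t", index=False)
    if metabolites_path is not None:
        pd.DataFrame(
            [
                {"metabolite_id": mid, "ratio": r.ratio, "significant": r.significant}
                for mid, r in data.metabolite_records.items()
            ]
        ).to_csv(Path(metabolites_path), sep="\t", index=False)
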