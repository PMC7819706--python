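"""On-disk dataset layout and the in-memory container the pipeline consumes.

A dataset directory holds plain-text files only:

- ``tree.nwk`` — ultrametric species tree, branch lengths in MY
- ``species_table.tsv`` — species_id, clade_label, is_focal
- ``proteins.fasta`` — one representative protein per gene, header ``species_id|gene_id``
- ``pfam_annotations.tsv`` — species_id, gene_id, pfam_id, start, end (1-based inclusive)
- ``pfam_metadata.tsv`` — pfam_id, taxonomic_annotation, in_bacteria, in_archaea, abstract_text
- ``tm_helices.tsv`` — species_id, gene_id, helix_start, helix_end
- ``disorder_scores.tsv`` — species_id, gene_id, position (1-based), score
- ``luca_pfams.txt`` — one pfam id per line
- ``truth.tsv`` — (synthetic datasets only) the generating truth table
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .age_assignment import StratumConfig
from .tree import TimeTree

__all__ = ["Dataset", "read_dataset", "write_dataset"]


@dataclass
class Dataset:
    """All inputs for one pipeline run."""

    tree: TimeTree
    species: pd.DataFrame
    annotations: pd.DataFrame
    sequences: dict[tuple[str, str], str]
    disorder: dict[tuple[str, str], np.ndarray]
    metadata: pd.DataFrame
    helices: pd.DataFrame
    luca_pfams: set[str]
    stratum: StratumConfig = field(default_factory=StratumConfig)
    truth: pd.DataFrame | None = None

    @property
    def clades(self) -> dict[str, str]:
        return dict(zip(self.species["species_id"], self.species["clade_label"]))

    @property
    def focal_species(self) -> set[str]:
        return set(self.species.loc[self.species["is_focal"], "species_id"])


def write_dataset(dataset: Dataset, out_dir) -> Path:
    """Write every dataset component as plain text; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.tree.write(out / "tree.nwk")
    dataset.species.to_csv(out / "species_table.tsv", sep="\t", index=False)
    dataset.annotations.to_csv(out / "pfam_annotations.tsv", sep="\t", index=False)
    dataset.metadata.to_csv(out / "pfam_metadata.tsv", sep="\t", index=False)
    dataset.helices.to_csv(out / "tm_helices.tsv", sep="\t", index=False)
    records = [
        SeqRecord(Seq(seq), id=f"{sp}|{gene}", description="")
        for (sp, gene), seq in sorted(dataset.sequences.items())
    ]
    SeqIO.write(records, out / "proteins.fasta", "fasta")
    rows = []
    for (sp, gene), scores in sorted(dataset.disorder.items()):
        rows.append(
            pd.DataFrame(
                {
                    "species_id": sp,
                    "gene_id": gene,
                    "position": np.arange(1, len(scores) + 1),
                    "score": np.round(scores, 6),
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(
        out / "disorder_scores.tsv", sep="\t", index=False
    )
    (out / "luca_pfams.txt").write_text(
        "".join(f"{p}\n" for p in sorted(dataset.luca_pfams))
    )
    if dataset.truth is not None:
        dataset.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return out


def read_dataset(in_dir, stratum: StratumConfig | None = None) -> Dataset:
    """Load a dataset directory written by :func:`write_dataset` (or by hand)."""
    d = Path(in_dir)
    tree = TimeTree.from_file(d / "tree.nwk")
    species = pd.read_csv(d / "species_table.tsv", sep="\t")
    annotations = pd.read_csv(d / "pfam_annotations.tsv", sep="\t")
    metadata = pd.read_csv(d / "pfam_metadata.tsv", sep="\t")
    metadata["abstract_text"] = metadata["abstract_text"].where(
        metadata["abstract_text"].notna(), None
    )
    helices = pd.read_csv(d / "tm_helices.tsv", sep="\t")
    sequences = {}
    for rec in SeqIO.parse(str(d / "proteins.fasta"), "fasta"):
        sp, gene = rec.id.split("|", 1)
        sequences[(sp, gene)] = str(rec.seq)
    disorder: dict[tuple[str, str], np.ndarray] = {}
    dis = pd.read_csv(d / "disorder_scores.tsv", sep="\t")
    for (sp, gene), grp in dis.groupby(["species_id", "gene_id"], sort=False):
        disorder[(sp, gene)] = grp.sort_values("position")["score"].to_numpy()
    luca_path = d / "luca_pfams.txt"
    luca = set(luca_path.read_text().split()) if luca_path.exists() else set()
    truth_path = d / "truth.tsv"
    truth = pd.read_csv(truth_path, sep="\t") if truth_path.exists() else None
    return Dataset(
        tree=tree,
        species=species,
        annotations=annotations,
        sequences=sequences,
        disorder=disorder,
        metadata=metadata,
        helices=helices,
        luca_pfams=luca,
        stratum=stratum or StratumConfig(luca_pfam_list=frozenset(luca)),
        truth=truth,
    )
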