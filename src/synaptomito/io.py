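"""Readers and writers for the plain-text formats used across the pipeline.

All tables are TSV/CSV so that runs are diffable and reproducible byte-for-byte.
Gene sets use the standard GMT format (name, description, then member IDs,
tab-separated, one set per line).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

FLOAT_FORMAT = "%.6g"

MORPHO_COLUMNS = [
    "animal_id",
    "genotype",
    "synapse_id",
    "compartment",
    "has_mito",
    "area_um2",
    "perimeter_um",
    "distance_nm",
    "synapse_length_nm",
]


# ---------------------------------------------------------------------------
# peptide tables


def write_peptide_table(pt, path) -> None:
    """Write a PeptideTable as TSV: peptide_id, protein_id, per-sample
    intensities, then per-sample ``<sample>_qvalue`` columns."""
    frame = pt.to_frame()
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_peptide_table(path):
    from .quantify import PeptideTable

    frame = pd.read_csv(path, sep="\t")
    return PeptideTable.from_frame(frame)


# ---------------------------------------------------------------------------
# design tables


def write_design(design, path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_design(path):
    from .quantify import GroupDesign

    return GroupDesign.from_frame(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# protein matrices


def write_protein_matrix(pm, path) -> None:
    frame = pm.log2.copy()
    frame.insert(0, "protein_id", frame.index)
    frame["n_peptides"] = pm.n_peptides.reindex(pm.log2.index).values
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_protein_matrix(path, normalized: bool = False):
    from .quantify import ProteinMatrix

    frame = pd.read_csv(path, sep="\t")
    frame = frame.set_index("protein_id")
    n_pep = frame.pop("n_peptides")
    return ProteinMatrix(log2=frame, n_peptides=n_pep, normalized=normalized)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> list:
    """Read a GMT file into a list of AnnotationSet objects."""
    from .mitotest import AnnotationSet

    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (needs >=3 fields): {line!r}")
        name, source = parts[0], parts[1]
        members = {m for m in parts[2:] if m}
        sets.append(AnnotationSet(name=name, members=members, source=source))
    return sets


def write_gmt(sets: Iterable, path) -> None:
    lines = []
    for s in sets:
        members = "\t".join(sorted(s.members))
        lines.append(f"{s.name}\t{s.source}\t{members}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# morphometry records


def write_morphometry(records: pd.DataFrame, path) -> None:
    # full precision: the perimeter/area isoperimetric identity must survive
    # the round trip
    records.to_csv(path, index=False, float_format="%.12g")


def read_morphometry(path) -> pd.DataFrame:
    records = pd.read_csv(path)
    missing = set(MORPHO_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"morphometry CSV missing columns: {sorted(missing)}")
    return records


# ---------------------------------------------------------------------------
# single-cell counts and labels


def write_counts(counts: pd.DataFrame, path) -> None:
    """Genes x cells count matrix as TSV with a leading ``gene`` column."""
    out = counts.copy()
    out.insert(0, "gene", out.index)
    out.to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t")
    return counts.set_index("gene")


def write_labels(labels: pd.Series, path) -> None:
    frame = labels.rename("cell_type").rename_axis("cell_id").reset_index()
    frame.to_csv(path, sep="\t", index=False)


def read_labels(path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t")
    return frame.set_index("cell_id")["cell_type"]


# ---------------------------------------------------------------------------
# configs


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    return json.loads(text)


def dump_json(obj: Mapping, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
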