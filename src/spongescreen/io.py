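"""Readers and writers for the pipeline's plain-text formats.

All tables are TSV.  Files written by the pipeline start with provenance
comment lines (``# key: value``: tool version, config hash, seed) which
every reader skips.  Expression files carry a ``!condition`` row right
after the header assigning tumor/normal labels to samples.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cerna import InteractionTable
from .enrichment import GeneSet
from .matrix import ExpressionMatrix
from .simulate import SimConfig, SimTruth, simulate_ct_table, \
    simulate_clinical, simulate_expression, simulate_fractions, \
    simulate_interaction_tables

CONDITION_ROW = "!condition"


def provenance_lines(meta: dict | None = None) -> list:
    lines = [f"# spongescreen {__version__}"]
    for key, value in (meta or {}).items():
        lines.append(f"# {key}: {value}")
    return lines


def _write_with_header(path, meta, body: str) -> None:
    with open(path, "w") as fh:
        for line in provenance_lines(meta):
            fh.write(line + "\n")
        fh.write(body)


# ---------------------------------------------------------------------------
# expression matrices


def write_expression_tsv(expr: ExpressionMatrix, path, meta=None) -> None:
    lines = ["gene_id\t" + "\t".join(expr.sample_ids)]
    lines.append(CONDITION_ROW + "\t" + "\t".join(expr.condition))
    for gene in expr.gene_ids:
        row = expr.values.loc[gene]
        lines.append(gene + "\t" + "\t".join(repr(float(v)) for v in row))
    _write_with_header(path, meta, "\n".join(lines) + "\n")


def read_expression_tsv(path, scale: str = "counts",
                        condition=None) -> ExpressionMatrix:
    """Parse a genes x samples TSV into an :class:`ExpressionMatrix`.

    The first non-comment line must be ``gene_id`` plus sample ids; a
    ``!condition`` row supplies labels unless ``condition`` (a mapping
    sample -> label) is given.  Ragged rows, duplicate ids and
    non-numeric cells are rejected with their coordinates.
    """
    path = Path(path)
    rows = []
    header = None
    cond_row = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            if len(fields) != len(header):
                raise ValueError(
                    f"{path.name}:{lineno}: ragged row ({len(fields)} fields, "
                    f"expected {len(header)})")
            if fields[0] == CONDITION_ROW:
                cond_row = fields[1:]
                continue
            rows.append((lineno, fields))
    if header is None or not rows:
        raise ValueError(f"{path.name}: no data rows")
    sample_ids = header[1:]
    gene_ids = []
    data = np.empty((len(rows), len(sample_ids)))
    seen = set()
    for i, (lineno, fields) in enumerate(rows):
        gid = fields[0]
        if gid in seen:
            raise ValueError(f"{path.name}:{lineno}: duplicate gene id {gid!r}")
        seen.add(gid)
        gene_ids.append(gid)
        for j, cell in enumerate(fields[1:]):
            try:
                data[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path.name}:{lineno}: non-numeric cell {cell!r} in "
                    f"column {sample_ids[j]!r}") from None
    if condition is not None:
        cond = pd.Series(condition).reindex(sample_ids)
    elif cond_row is not None:
        cond = pd.Series(cond_row, index=sample_ids)
    else:
        raise ValueError(f"{path.name}: no condition row and no condition map")
    values = pd.DataFrame(data, index=gene_ids, columns=sample_ids)
    return ExpressionMatrix(values=values, condition=cond, scale=scale)


# ---------------------------------------------------------------------------
# generic tables


def write_table_tsv(frame: pd.DataFrame, path, meta=None,
                    index: bool = True) -> None:
    _write_with_header(path, meta, frame.to_csv(sep="\t", index=index))


def read_table_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


# ---------------------------------------------------------------------------
# interaction tables


def write_interaction_tsv(tables, path, meta=None) -> None:
    rows = []
    for table in tables:
        for r, t in sorted(table.edges):
            rows.append(f"{r}\t{t}\t{table.source_db}")
    body = "regulator_id\ttarget_id\tsource_db\n" + "\n".join(rows) + "\n"
    _write_with_header(path, meta, body)


def read_interaction_tsv(path, edge_class: str) -> list:
    """One :class:`InteractionTable` per distinct source_db in the file."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"regulator_id", "target_id", "source_db"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{Path(path).name}: need columns {sorted(required)}")
    tables = []
    for source, sub in frame.groupby("source_db", sort=True):
        edges = set(zip(sub["regulator_id"], sub["target_id"]))
        tables.append(InteractionTable(edges=edges, edge_class=edge_class,
                                       source_db=str(source)))
    return tables


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path) -> list:
    """GMT: one set per line — name, description, then member ids."""
    sets = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{Path(path).name}:{lineno}: GMT line needs >= 3 fields")
            sets.append(GeneSet(name=fields[0], members=tuple(fields[2:])))
    return sets


def write_gmt(gene_sets, path) -> None:
    with open(path, "w") as fh:
        for s in gene_sets:
            fh.write("\t".join([s.name, "na", *s.members]) + "\n")


# ---------------------------------------------------------------------------
# truth JSON


def write_truth_json(truth: SimTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth_json(path) -> SimTruth:
    with open(path) as fh:
        return SimTruth.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# synthetic bundle


def write_bundle(config: SimConfig, outdir) -> dict:
    """Generate and write the full synthetic input bundle.

    Emits expression counts, interaction tables, clinical table, immune
    fractions, a qPCR plate, a small GMT built around the planted hub,
    and the truth JSON.  Returns the path map plus the truth record.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "generator": "synthetic bundle"}
    expr, truth = simulate_expression(config)
    tables = simulate_interaction_tables(truth, config)
    clinical = simulate_clinical(expr, truth, config)
    fractions = simulate_fractions(expr, truth, config)
    ct = simulate_ct_table(config)

    paths = {
        "expression": outdir / "expression_counts.tsv",
        "lnc_mi": outdir / "interactions_lnc_mi.tsv",
        "mi_mrna": outdir / "interactions_mi_mrna.tsv",
        "clinical": outdir / "clinical.tsv",
        "fractions": outdir / "fractions.tsv",
        "ct": outdir / "qpcr_ct.tsv",
        "gmt": outdir / "gene_sets.gmt",
        "truth": outdir / "truth.json",
    }
    write_expression_tsv(expr, paths["expression"], meta)
    write_interaction_tsv(tables["lnc_mi"], paths["lnc_mi"], meta)
    write_interaction_tsv(tables["mi_mrna"], paths["mi_mrna"], meta)
    write_table_tsv(clinical, paths["clinical"], meta)
    write_table_tsv(fractions, paths["fractions"], meta)
    write_table_tsv(ct, paths["ct"], meta, index=False)

    mrnas = [g for g in expr.gene_ids if g.startswith("MR")]
    decoys = [g for g in mrnas if g not in set(truth.ligands)]
    hub_set = GeneSet("HUB_COEXPRESSION_SIM",
                      tuple(truth.ligands) + tuple(decoys[:4]))
    random_set = GeneSet("RANDOM_SET_SIM", tuple(decoys[10:25]))
    tam_set = GeneSet("TAM_SIGNATURE_SIM",
                      tuple(truth.ligands) + tuple(decoys[4:10]))
    write_gmt([hub_set, random_set, tam_set], paths["gmt"])
    write_truth_json(truth, paths["truth"])
    return {"paths": {k: str(v) for k, v in paths.items()}, "truth": truth,
            "expr": expr, "clinical": clinical, "fractions": fractions}
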