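"""Readers and writers for every external format the pipeline touches.

Formats are deliberately plain text so inputs stay hand-writable:

* expression table — TSV with paired columns ``<sample>`` (signal) and
  ``<sample>.call`` (detection call); the group map travels separately as
  YAML or two-column TSV;
* gene sets — standard GMT (name, description, members);
* interaction network — SIF (``A rel B``) or two-column TSV edge list;
* gene annotations — TSV (gene_id, symbol, entrez_name, compartment,
  molecule_type);
* results tables — TSV with fold changes rendered to two decimals and the
  "~" marker for a gene that did not qualify as changed on that side.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from ._rounding import round_half_up
from .datatypes import (
    CALL_SYMBOLS,
    ConfigurationError,
    ExpressionDataset,
    FormatError,
    GeneAnnotation,
    GeneSetCollection,
    InteractionNetwork,
)

logger = logging.getLogger(__name__)

#: Serialization for "no qualifying change" in fold-change cells.
NO_CHANGE_MARKER = "~"


def format_fold(value: float | None) -> str:
    """Render a signed fold change to two decimals, or "~" when absent."""
    if value is None:
        return NO_CHANGE_MARKER
    return f"{round_half_up(value, 2):.2f}"


def parse_fold(text: str) -> float | None:
    """Inverse of :func:`format_fold`."""
    text = text.strip()
    if text == NO_CHANGE_MARKER:
        return None
    return float(text)


# ---------------------------------------------------------------------------
# expression table


def read_expression_table(
    path: str | Path, group_map: Mapping[str, str]
) -> ExpressionDataset:
    """Read a signal+call expression table.

    The header names the sample columns; each sample must appear as a signal
    column ``<sample>`` immediately followed by its call column
    ``<sample>.call``. Every sample must be present in ``group_map``.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3:
            raise FormatError(f"{path}: expected gene id plus sample columns")
        sample_ids: list[str] = []
        col = 1
        while col < len(header):
            sample = header[col]
            if col + 1 >= len(header) or header[col + 1] != f"{sample}.call":
                raise FormatError(
                    f"{path}: sample {sample!r} lacks a matching "
                    f"'{sample}.call' column"
                )
            sample_ids.append(sample)
            col += 2
        missing = [s for s in sample_ids if s not in group_map]
        if missing:
            raise ConfigurationError(
                f"{path}: sample(s) not in group map: {', '.join(missing)}"
            )

        gene_ids: list[str] = []
        signals: list[list[float]] = []
        calls: list[list[str]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 1 + 2 * len(sample_ids):
                raise FormatError(
                    f"{path}:{lineno}: expected {1 + 2 * len(sample_ids)} "
                    f"fields, got {len(fields)}"
                )
            gene_ids.append(fields[0].strip())
            sig_row: list[float] = []
            call_row: list[str] = []
            for j, sample in enumerate(sample_ids):
                raw_sig = fields[1 + 2 * j]
                raw_call = fields[2 + 2 * j].strip()
                try:
                    sig_row.append(float(raw_sig))
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric signal {raw_sig!r} "
                        f"for gene {fields[0]!r}, sample {sample!r}"
                    ) from None
                if raw_call not in CALL_SYMBOLS:
                    raise FormatError(
                        f"{path}:{lineno}: unknown detection call "
                        f"{raw_call!r} for gene {fields[0]!r}, sample {sample!r}"
                    )
                call_row.append(raw_call)
            signals.append(sig_row)
            calls.append(call_row)

    return ExpressionDataset(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        group_of_sample={s: group_map[s] for s in sample_ids},
        signal=np.asarray(signals, dtype=float),
        call=np.asarray(calls, dtype=object),
    )


def write_expression_table(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write a dataset in the paired signal/call dialect read back by
    :func:`read_expression_table`."""
    path = Path(path)
    with path.open("w") as fh:
        header = ["gene_id"]
        for s in dataset.sample_ids:
            header += [s, f"{s}.call"]
        fh.write("\t".join(header) + "\n")
        for i, gene in enumerate(dataset.gene_ids):
            fields = [gene]
            for j in range(dataset.n_samples):
                fields.append(repr(float(dataset.signal[i, j])))
                fields.append(str(dataset.call[i, j]))
            fh.write("\t".join(fields) + "\n")


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a sample-to-group map from YAML (mapping) or two-column TSV."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        data = yaml.safe_load(path.read_text())
        if not isinstance(data, dict):
            raise FormatError(f"{path}: expected a YAML mapping sample -> group")
        return {str(k): str(v) for k, v in data.items()}
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 'sample<TAB>group'")
        mapping[fields[0].strip()] = fields[1].strip()
    return mapping


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gene_sets(
    path: str | Path, ir_set_name: str | None = None
) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, member symbols."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line needs name, description and at "
                f"least one member ({len(fields)} fields found)"
            )
        name = fields[0].strip()
        members = {f.strip() for f in fields[2:] if f.strip()}
        if not members:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
        sets[name] = members
    return GeneSetCollection(sets, ir_set_name=ir_set_name)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name in sorted(collection.sets):
            members = sorted(collection.sets[name])
            fh.write("\t".join([name, "na", *members]) + "\n")


# ---------------------------------------------------------------------------
# interaction network (SIF / TSV edge list)


def read_network(path: str | Path) -> InteractionNetwork:
    """Read an undirected network from SIF ("A rel B") or 2-column TSV.

    Duplicate and reversed edges collapse to one; self-loops are dropped
    with a warning. Lines with a single field declare an isolated node.
    """
    path = Path(path)
    net = InteractionNetwork()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        fields = [f.strip() for f in fields]
        if any(not f for f in fields):
            raise FormatError(f"{path}:{lineno}: blank node name")
        if len(fields) == 1:
            net.add_node(fields[0])
        elif len(fields) == 2:  # plain edge list
            if not net.add_edge(fields[0], fields[1]):
                logger.warning("%s:%d: dropped self-loop on %r", path, lineno, fields[0])
        elif len(fields) >= 3:  # SIF: source, relation, targets...
            source = fields[0]
            for target in fields[2:]:
                if not net.add_edge(source, target):
                    logger.warning(
                        "%s:%d: dropped self-loop on %r", path, lineno, source
                    )
        else:
            raise FormatError(f"{path}:{lineno}: unparseable line")
    return net


def write_network(net: InteractionNetwork, path: str | Path) -> None:
    """Write as SIF with the generic 'pp' relation; isolated nodes as bare names."""
    path = Path(path)
    with path.open("w") as fh:
        for edge in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{edge[0]}\tpp\t{edge[1]}\n")
        connected = {n for e in net.edges for n in e}
        for node in sorted(net.nodes - connected):
            fh.write(f"{node}\n")


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path: str | Path) -> dict[str, GeneAnnotation]:
    """Read a gene annotation TSV keyed by gene_id; first annotation wins."""
    path = Path(path)
    annotations: dict[str, GeneAnnotation] = {}
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty annotation table")
    header = [h.strip() for h in lines[0].split("\t")]
    required = {"gene_id", "symbol", "compartment", "molecule_type"}
    if not required.issubset(header):
        raise FormatError(
            f"{path}: annotation header must contain {sorted(required)}"
        )
    idx = {h: i for i, h in enumerate(header)}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        gene_id = fields[idx["gene_id"]].strip()
        if gene_id in annotations:
            continue
        annotations[gene_id] = GeneAnnotation(
            gene_id=gene_id,
            symbol=fields[idx["symbol"]].strip(),
            entrez_name=(
                fields[idx["entrez_name"]].strip() if "entrez_name" in idx else ""
            ),
            compartment=fields[idx["compartment"]].strip(),
            molecule_type=fields[idx["molecule_type"]].strip(),
        )
    return annotations


def write_annotations(
    annotations: Mapping[str, GeneAnnotation], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\tsymbol\tentrez_name\tcompartment\tmolecule_type\n")
        for gene_id in sorted(annotations):
            a = annotations[gene_id]
            fh.write(
                "\t".join(
                    [a.gene_id, a.symbol, a.entrez_name, a.compartment, a.molecule_type]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# generic results tables


def write_results_table(
    records: Sequence[Mapping[str, object]],
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write downstream records as a deterministic TSV.

    ``records`` are mappings; ``columns`` fixes the column order (defaults to
    the key order of the first record). Float cells are rendered to two
    decimals half-up; ``None`` fold-change cells render as "~"; an empty
    record list yields a header-only file (requires explicit ``columns``).
    """
    path = Path(path)
    if columns is None:
        if not records:
            raise ConfigurationError(
                "empty record list requires explicit column names"
            )
        columns = list(records[0].keys())
    with path.open("w") as fh:
        fh.write("\t".join(columns) + "\n")
        for rec in records:
            cells = []
            for c in columns:
                v = rec.get(c)
                if v is None:
                    cells.append(NO_CHANGE_MARKER)
                elif isinstance(v, float):
                    cells.append(format_fold(v))
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")


def fold_change_cell(fc_ipsi: float | None, fc_contra: float | None) -> str:
    """Render the combined "TBI-I | TBI-C" fold-change cell, e.g. "3.37 | ~"."""
    return f"{format_fold(fc_ipsi)} | {format_fold(fc_contra)}"
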