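"""Peptidome input/output.

Reads protein FASTA files and flat peptide quantification tables (CSV/TSV),
maps peptides onto their parent protein, log-normalizes intensities onto the
probability simplex, and round-trips graph artifacts as JSON.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .graph import DegradationGraph, PeptideNode

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinRecord",
    "PeptideMeasurement",
    "PeptidomeTable",
    "TableOptions",
    "NormalizeOptions",
    "read_fasta",
    "read_peptide_table",
    "write_peptide_table",
    "normalize_abundances",
    "write_graph_json",
    "read_graph_json",
]

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinRecord:
    """A parent protein: identifier plus one-letter amino-acid sequence."""

    identifier: str
    sequence: str
    extra_residues: frozenset[str] = frozenset({"X", "U", "B", "Z"})

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.identifier!r} has empty sequence")
        allowed = STANDARD_RESIDUES | set(self.extra_residues)
        bad = set(self.sequence) - allowed
        if bad:
            raise ValueError(
                f"protein {self.identifier!r} contains invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PeptideMeasurement:
    """One peptide row: sequence, placement, and per-sample intensities."""

    sequence: str
    start: int | None
    end: int | None
    intensity_per_sample: dict[str, float]

    def __post_init__(self) -> None:
        for sample, x in self.intensity_per_sample.items():
            if x < 0 or not math.isfinite(x):
                raise ValueError(
                    f"negative or non-finite intensity {x} for peptide "
                    f"{self.sequence!r}, sample {sample!r}"
                )


@dataclass
class PeptidomeTable:
    protein: ProteinRecord
    measurements: list[PeptideMeasurement]
    samples: list[str]


@dataclass
class TableOptions:
    """Parsing options for :func:`read_peptide_table`.

    ``intensity_pattern`` is a regex matched against column names; by default
    every column other than the peptide/start/end columns is an intensity
    column.  ``duplicate_policy`` resolves peptides that occur at several
    positions in the protein: ``"leftmost"`` (deterministic default) or
    ``"split"`` (duplicate across all occurrences with intensity divided
    equally).
    """

    peptide_column: str = "peptide"
    start_column: str = "start"
    end_column: str = "end"
    intensity_pattern: str | None = None
    duplicate_policy: str = "leftmost"
    delimiter: str | None = None


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    The identifier is the header up to the first whitespace; sequences are
    uppercased and may span multiple lines.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: line {lineno}: expected FASTA header '>', "
                        f"got {line.strip()[:30]!r}"
                    )
                break
        else:
            raise ValueError(f"{path}: empty FASTA file")
    records = [
        ProteinRecord(identifier=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(path, "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def _find_occurrences(protein: str, peptide: str) -> list[int]:
    hits, i = [], protein.find(peptide)
    while i != -1:
        hits.append(i)
        i = protein.find(peptide, i + 1)
    return hits


def read_peptide_table(
    path: str | Path,
    protein: ProteinRecord,
    options: TableOptions | None = None,
) -> PeptidomeTable:
    """Read a delimited peptide quantification table and map it onto a protein.

    Peptides absent from the protein sequence are dropped with a warning;
    peptides with multiple placements are resolved per
    ``options.duplicate_policy``.  Rows sharing a placement are summed.
    """
    opts = options or TableOptions()
    path = Path(path)
    sep = opts.delimiter
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if opts.peptide_column not in df.columns:
        raise ValueError(f"{path}: missing peptide column {opts.peptide_column!r}")
    reserved = {opts.peptide_column, opts.start_column, opts.end_column}
    if opts.intensity_pattern is not None:
        pat = re.compile(opts.intensity_pattern)
        samples = [c for c in df.columns if c not in reserved and pat.search(c)]
    else:
        samples = [c for c in df.columns if c not in reserved]
    if not samples:
        raise ValueError(f"{path}: no intensity columns found")

    has_pos = opts.start_column in df.columns and opts.end_column in df.columns
    placed: dict[tuple[int, int], PeptideMeasurement] = {}
    n_dropped = 0
    for _, row in df.iterrows():
        pep = str(row[opts.peptide_column]).strip().upper()
        intensities = {
            s: 0.0 if pd.isna(row[s]) else float(row[s]) for s in samples
        }
        if any(x < 0 for x in intensities.values()):
            raise ValueError(f"negative intensity for peptide {pep!r}")
        if has_pos and not pd.isna(row[opts.start_column]):
            s0, e0 = int(row[opts.start_column]), int(row[opts.end_column])
            if protein.sequence[s0:e0] != pep:
                logger.warning(
                    "peptide %r does not match protein %s at [%d, %d); dropped",
                    pep, protein.identifier, s0, e0,
                )
                n_dropped += 1
                continue
            placements = [(s0, e0, 1.0)]
        else:
            occ = _find_occurrences(protein.sequence, pep)
            if not occ:
                logger.warning(
                    "peptide %r not found in protein %s; dropped",
                    pep, protein.identifier,
                )
                n_dropped += 1
                continue
            if opts.duplicate_policy == "leftmost" or len(occ) == 1:
                placements = [(occ[0], occ[0] + len(pep), 1.0)]
            elif opts.duplicate_policy == "split":
                placements = [(i, i + len(pep), 1.0 / len(occ)) for i in occ]
            else:
                raise ValueError(f"unknown duplicate policy {opts.duplicate_policy!r}")
        for s0, e0, frac in placements:
            key = (s0, e0)
            scaled = {s: x * frac for s, x in intensities.items()}
            if key in placed:
                for s in samples:
                    placed[key].intensity_per_sample[s] += scaled[s]
            else:
                placed[key] = PeptideMeasurement(
                    sequence=protein.sequence[s0:e0],
                    start=s0,
                    end=e0,
                    intensity_per_sample=scaled,
                )
    if not placed:
        raise ValueError(
            f"{path}: no peptide maps to protein {protein.identifier} "
            f"({n_dropped} dropped)"
        )
    measurements = [placed[k] for k in sorted(placed)]
    return PeptidomeTable(protein=protein, measurements=measurements, samples=samples)


def write_peptide_table(
    table: PeptidomeTable, path: str | Path, options: TableOptions | None = None
) -> None:
    """Write a :class:`PeptidomeTable` back to delimited text (round-trip)."""
    opts = options or TableOptions()
    path = Path(path)
    sep = opts.delimiter
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    rows = [
        {
            opts.peptide_column: m.sequence,
            opts.start_column: m.start,
            opts.end_column: m.end,
            **m.intensity_per_sample,
        }
        for m in table.measurements
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


@dataclass
class NormalizeOptions:
    """Log-transform and imputation settings.

    ``log=True`` applies the natural log (configurable base) to raw
    intensities before simplex rescaling; missing/zero intensities are
    imputed at the ``impute_quantile`` quantile of the observed
    log-intensities.
    """

    log: bool = True
    log_base: float = math.e
    impute_quantile: float = 0.01


def normalize_abundances(
    table: PeptidomeTable,
    sample: str | None = None,
    options: NormalizeOptions | None = None,
) -> dict[tuple[int, int], float]:
    """Normalized abundance per peptide interval for one sample.

    ``sample=None`` averages raw intensities across all samples (as done for
    in-vitro digests); otherwise the named sample is used (one distribution,
    and downstream one graph, per sample).  Intensities are log-transformed,
    missing values imputed at the configured lowest quantile of the observed
    log-intensities, and the result rescaled to sum to exactly 1.
    """
    opts = options or NormalizeOptions()
    if sample is not None and sample not in table.samples:
        raise KeyError(f"sample {sample!r} not in table (have {table.samples})")

    def raw(m: PeptideMeasurement) -> float:
        if sample is None:
            return float(np.mean(list(m.intensity_per_sample.values())))
        return m.intensity_per_sample[sample]

    raw_vals = {(m.start, m.end): raw(m) for m in table.measurements}
    observed = [x for x in raw_vals.values() if x > 0]
    if not observed:
        raise ValueError("all intensities are zero or missing")
    if opts.log:
        logs = [math.log(x, opts.log_base) for x in observed]
        fill = float(np.quantile(logs, opts.impute_quantile))
        vals = {
            k: (math.log(x, opts.log_base) if x > 0 else fill)
            for k, x in raw_vals.items()
        }
    else:
        fill = float(np.quantile(observed, opts.impute_quantile))
        vals = {k: (x if x > 0 else fill) for k, x in raw_vals.items()}
    if min(vals.values()) < 0:
        raise ValueError(
            "log-intensities include negative values; rescale raw intensities "
            "(weights must lie in [0, 1])"
        )
    total = sum(vals.values())
    if total <= 0:
        raise ValueError("all normalized intensities are zero")
    return {k: v / total for k, v in vals.items()}


# ---------------------------------------------------------------------------
# graph JSON artifact


def write_graph_json(
    graph: DegradationGraph,
    path: str | Path,
    flows: np.ndarray | None = None,
    metadata: dict | None = None,
) -> None:
    """Serialize a graph (and optional per-edge flows) to the JSON artifact."""
    doc = {
        "metadata": {"protein_id": graph.protein_id, **(metadata or {})},
        "nodes": [
            {
                "id": n.id,
                "start": n.start,
                "end": n.end,
                "sequence": n.sequence,
                "abundance": n.observed_abundance,
            }
            for n in graph.nodes
        ],
        "edges": [
            {
                "source": int(u),
                "target": int(v),
                "weight": float(graph.weights[e]),
                "flow": None if flows is None else float(flows[e]),
            }
            for e, (u, v) in enumerate(graph.edges)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_graph_json(path: str | Path):
    """Load the JSON artifact back into a graph (+ flows, metadata)."""
    doc = json.loads(Path(path).read_text())
    nodes = [
        PeptideNode(
            id=nd["id"],
            start=nd["start"],
            end=nd["end"],
            sequence=nd["sequence"],
            observed_abundance=nd["abundance"],
        )
        for nd in sorted(doc["nodes"], key=lambda d: d["id"])
    ]
    edges = [(ed["source"], ed["target"]) for ed in doc["edges"]]
    weights = np.array([ed["weight"] for ed in doc["edges"]], dtype=float)
    graph = DegradationGraph(
        nodes, edges, weights, protein_id=doc["metadata"].get("protein_id", "")
    )
    raw_flows = [ed.get("flow") for ed in doc["edges"]]
    flows = (
        None
        if any(f is None for f in raw_flows) or not raw_flows
        else np.array(raw_flows, dtype=float)
    )
    return graph, flows, doc["metadata"]
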