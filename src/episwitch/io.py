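"""Table readers/writers and run configuration.

All tables are plain UTF-8 CSV/TSV with a header row, '.' decimal and the
NA token ``NA``.  Validation errors name the offending table line.
"""

from __future__ import annotations

import difflib
import logging
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .lineage import LineageTree, TreeStructureError
from .spatial import MonolayerField
from .traces import CellTrace

__all__ = [
    "parse_lineage_table",
    "write_lineage_table",
    "parse_trace_table",
    "write_trace_table",
    "parse_position_table",
    "write_position_table",
    "RunConfig",
    "load_config",
]

logger = logging.getLogger(__name__)

_LINEAGE_COLUMNS = (
    "lineage_id", "node_id", "parent_id", "generation", "fate", "leaf_status",
)
_TRACE_COLUMNS = (
    "cell_id", "frame", "time_min", "nuc_p65", "cyt_p65", "venus",
    "stimulus", "concentration", "t_stim_min",
)
_POSITION_COLUMNS = ("cell_id", "x_um", "y_um", "responder", "field_id")


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required columns {missing}")


# ---------------------------------------------------------------------------
# Lineage tables
# ---------------------------------------------------------------------------


def parse_lineage_table(path) -> list[LineageTree]:
    """Read a lineage TSV into validated trees (one per ``lineage_id``).

    Row order is irrelevant.  Structural violations (orphan parents, a
    divided node without exactly two children, status on an internal node)
    raise with the first offending table line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, _LINEAGE_COLUMNS, "lineage table")
    trees = []
    for lid, sub in df.groupby("lineage_id", sort=True):
        records = sub.to_dict("records")
        try:
            tree = LineageTree.from_records(records, tree_id=str(lid))
        except (TreeStructureError, KeyError) as exc:
            first_line = int(sub.index[0]) + 2  # header + 1-based
            raise TreeStructureError(
                f"lineage {lid!r} (starting at line {first_line}): {exc}"
            ) from exc
        trees.append(tree)
    if not trees:
        raise ValueError("lineage table contains no rows")
    return trees


def write_lineage_table(trees: Sequence[LineageTree], path) -> None:
    rows = []
    for tree in trees:
        for rec in tree.to_records():
            status = rec["leaf_status"]
            rows.append(
                {
                    "lineage_id": tree.tree_id,
                    **rec,
                    "leaf_status": {"responder": "R", "non_responder": "N",
                                    "unknown": "NA"}[status],
                }
            )
    pd.DataFrame(rows, columns=_LINEAGE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Trace tables (long format)
# ---------------------------------------------------------------------------


def parse_trace_table(path) -> list[CellTrace]:
    """Read a long-format trace CSV into per-cell traces, time-sorted.

    Rejects duplicated (cell_id, frame) rows, non-monotone frame times and
    mixed frame intervals within a cell.
    """
    df = pd.read_csv(path)
    _require_columns(df, _TRACE_COLUMNS, "trace table")
    dup = df.duplicated(subset=["cell_id", "frame"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise ValueError(f"trace table: duplicated (cell_id, frame) at line {line}")
    traces = []
    for cid, sub in df.groupby("cell_id", sort=True):
        sub = sub.sort_values("frame")
        t = sub["time_min"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"trace table: cell {cid!r} has non-monotone time_min")
        steps = np.diff(t)
        if len(steps) and not np.allclose(steps, steps[0]):
            raise ValueError(f"trace table: cell {cid!r} has mixed frame intervals")
        nuc = sub["nuc_p65"].to_numpy(dtype=float)
        cyt = sub["cyt_p65"].to_numpy(dtype=float)
        traces.append(
            CellTrace(
                cell_id=str(cid),
                time_min=t,
                nc_ratio=nuc / cyt,
                reporter=sub["venus"].to_numpy(dtype=float),
                stimulus=str(sub["stimulus"].iloc[0]),
                concentration=float(sub["concentration"].iloc[0]),
                t_stim_min=float(sub["t_stim_min"].iloc[0]),
                nuc_p65=nuc,
                cyt_p65=cyt,
            )
        )
    return traces


def write_trace_table(traces: Sequence[CellTrace], path) -> None:
    frames = []
    for tr in traces:
        if tr.nuc_p65 is None or tr.cyt_p65 is None:
            raise ValueError(f"{tr.cell_id}: nuc/cyt p65 required to write table")
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "frame": np.arange(len(tr.time_min)),
                    "time_min": tr.time_min,
                    "nuc_p65": tr.nuc_p65,
                    "cyt_p65": tr.cyt_p65,
                    "venus": tr.reporter,
                    "stimulus": tr.stimulus,
                    "concentration": tr.concentration,
                    "t_stim_min": tr.t_stim_min,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Position tables
# ---------------------------------------------------------------------------


def parse_position_table(path) -> list[MonolayerField]:
    """Read a position CSV into one MonolayerField per field_id."""
    df = pd.read_csv(path)
    _require_columns(df, _POSITION_COLUMNS, "position table")
    fields_out = []
    for fid, sub in df.groupby("field_id", sort=True):
        fields_out.append(
            MonolayerField.from_arrays(
                sub[["x_um", "y_um"]].to_numpy(dtype=float),
                sub["responder"].to_numpy(dtype=int).astype(bool),
                field_id=str(fid),
            )
        )
    if not fields_out:
        raise ValueError("position table contains no rows")
    return fields_out


def write_position_table(fields_in: Sequence[MonolayerField], path) -> None:
    rows = []
    for f in fields_in:
        for i, (xy, lab) in enumerate(zip(f.positions, f.labels)):
            rows.append(
                {
                    "cell_id": f"{f.field_id}_c{i}",
                    "x_um": xy[0],
                    "y_um": xy[1],
                    "responder": int(lab),
                    "field_id": f.field_id,
                }
            )
    pd.DataFrame(rows, columns=_POSITION_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Methylation call tables
# ---------------------------------------------------------------------------


def write_methyl_call_table(
    matrix, tss: tuple[str, int, str], path, llr_mag: float = 3.0
) -> None:
    """Write a MethylReadMatrix as a nanopore-style per-read call TSV.

    Within a read, runs of same-call CpGs lying within 10 bp of each other
    are emitted as one motif-group row (``num_motifs`` > 1) with a synthetic
    sequence context whose CG offsets encode the per-CpG genomic positions;
    missing calls are simply not emitted.  Round-trips through
    ``methylation.read_call_table``.
    """
    from .methylation import MISSING, M as M_CODE

    chrom, tss_pos, strand = tss
    rows = []
    rels = matrix.cpg_positions
    genomic = tss_pos + rels if strand == "+" else tss_pos - rels
    order = np.argsort(genomic)
    for i, rid in enumerate(matrix.read_ids):
        runs: list[list[int]] = []
        prev_g = prev_call = None
        for j in order:
            call = int(matrix.calls[i, j])
            if call == MISSING:
                prev_g = prev_call = None
                continue
            g = int(genomic[j])
            if prev_call == call and prev_g is not None and g - prev_g < 10:
                runs[-1].append(j)
            else:
                runs.append([j])
            prev_g, prev_call = g, call
        for run in runs:
            gs = sorted(int(genomic[j]) for j in run)
            call = int(matrix.calls[i, run[0]])
            offsets = [g - gs[0] for g in gs]
            seq = ["T"] * (3 + offsets[-1] + 2 + 3)
            for o in offsets:
                seq[3 + o] = "C"
                seq[3 + o + 1] = "G"
            rows.append(
                {
                    "chromosome": chrom,
                    "strand": strand,
                    "start": gs[0],
                    "end": gs[-1],
                    "read_name": rid,
                    "log_lik_ratio": llr_mag if call == M_CODE else -llr_mag,
                    "num_motifs": len(run),
                    "sequence": "".join(seq),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Resolved stage parameters for a pipeline run.

    Unknown keys in the config file are rejected with a closest-match
    suggestion; the resolved configuration can be echoed to the output
    directory for provenance.
    """

    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"
    # lineage model
    p_on: float = 0.01
    p_off: float = 0.055
    initial_fraction: float | None = None
    n_lineages: int = 58
    max_generations: int = 5
    death_prob: float = 0.39
    root_dist: str = "free"
    ci_method: str = "profile"
    generation_time_h: float = 24.0
    f0: float = 0.65
    # responder calling
    responder_rule: str = "max"
    score_window_min: float | None = None
    qc_low_pct: float = 25.0
    qc_high_pct: float = 99.0
    # spatial test
    knn_k: int = 5
    n_perm: int = 1000
    # methylation
    llr_threshold: float = 1.5
    window_start: int = -110
    window_end: int = -60
    min_covered: float = 0.8
    enbloc_tolerance: int = 1
    # chi-squared comparison
    n_bins: int = 10

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, filling defaults.

    An empty file yields all defaults (with a warning); an unknown key
    raises with a suggestion for the closest known key.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        warnings.warn(f"{path}: empty config, using all defaults", stacklevel=2)
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    for key in data:
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suggestion = f" (did you mean {hint[0]!r}?)" if hint else ""
            raise ValueError(f"{path}: unknown config key {key!r}{suggestion}")
    typed = {}
    for f in fields(RunConfig):
        if f.name not in data:
            continue
        value = data[f.name]
        if value is not None and f.type in ("int", "float", "str"):
            caster = {"int": int, "float": float, "str": str}[f.type]
            try:
                value = caster(value)
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}: key {f.name!r} expects {f.type}, got {value!r}"
                ) from exc
        typed[f.name] = value
    return RunConfig(**typed)
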