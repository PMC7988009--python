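"""Per-read promoter CpG methylation: parsing, counting, and bimodality.

Nanopore methylation callers emit one log-likelihood ratio (LLR) per read
per CpG motif group; calls are accepted only when |LLR| > 1.5, and motif
groups whose CpGs lie within 10 bp of each other receive a single call for
the whole group.  Over a promoter window, single reads tend to be methylated
or unmethylated *en bloc*: the per-read count of unmethylated CpGs is
strongly bimodal, which a two-component binomial mixture quantifies.

Coordinates are TSS-relative (0 = transcription start, upstream negative,
strand-aware); window bounds are inclusive at both ends.  Genomic input
positions follow the 0-based convention of BED-like call tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "M",
    "U",
    "MISSING",
    "MethylReadMatrix",
    "PromoterWindow",
    "BinomialMixtureFit",
    "read_call_table",
    "window_unmethylated_counts",
    "methylation_percentages",
    "fit_binomial_mixture",
    "classify_enbloc",
]

logger = logging.getLogger(__name__)

# Call codes in the read x site matrix.
U: int = 0
M: int = 1
MISSING: int = -1

REQUIRED_COLUMNS = (
    "read_name",
    "chromosome",
    "strand",
    "start",
    "log_lik_ratio",
    "num_motifs",
    "sequence",
)


@dataclass(frozen=True)
class PromoterWindow:
    """Inclusive TSS-relative window, e.g. PromoterWindow(-110, -60)."""

    start_rel: int
    end_rel: int

    def __post_init__(self) -> None:
        if self.start_rel > self.end_rel:
            raise ValueError("start_rel must be <= end_rel")

    def contains(self, positions: np.ndarray) -> np.ndarray:
        positions = np.asarray(positions)
        return (positions >= self.start_rel) & (positions <= self.end_rel)


@dataclass
class MethylReadMatrix:
    """Per-read CpG calls over a region, TSS-relative columns."""

    read_ids: list[str]
    cpg_positions: np.ndarray  # strictly increasing, TSS-relative
    calls: np.ndarray  # (reads, sites) int8 over {U, M, MISSING}
    region_label: str = ""

    def __post_init__(self) -> None:
        self.cpg_positions = np.asarray(self.cpg_positions, dtype=int)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if np.any(np.diff(self.cpg_positions) <= 0):
            raise ValueError("cpg_positions must be strictly increasing")
        if self.calls.shape != (len(self.read_ids), len(self.cpg_positions)):
            raise ValueError("calls matrix shape inconsistent with ids/positions")
        if np.any(np.all(self.calls == MISSING, axis=1)):
            raise ValueError("every read must have >=1 non-missing call")

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.calls, index=self.read_ids, columns=self.cpg_positions
        )


def _cg_offsets(sequence: str) -> list[int]:
    return [i for i in range(len(sequence) - 1) if sequence[i : i + 2] == "CG"]


def read_call_table(
    path,
    tss: tuple[str, int, str],
    llr_threshold: float = 1.5,
    region_label: str = "",
) -> MethylReadMatrix:
    """Parse a nanopore-style per-read methylation call table.

    Parameters
    ----------
    path : str or file-like
        TSV with columns ``read_name, chromosome, strand, start,
        log_lik_ratio, num_motifs, sequence`` (0-based genomic ``start`` of
        the first CpG's C).
    tss : (chromosome, position, strand)
        Transcription start site used to convert genomic positions to
        TSS-relative coordinates (upstream negative, strand-aware).
    llr_threshold : float
        LLR > +threshold → methylated; LLR < −threshold → unmethylated;
        in between → missing (ambiguous call discarded).

    Rows with ``num_motifs > 1`` are motif groups: the single call is
    assigned to every CpG in the group, with per-CpG genomic positions read
    off the CG occurrences in the ``sequence`` context column.
    """
    df = pd.read_csv(path, sep="\t")
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"call table missing required columns: {missing_cols}")
    chrom, tss_pos, tss_strand = tss
    if tss_strand not in ("+", "-"):
        raise ValueError("tss strand must be '+' or '-'")
    df = df[df["chromosome"].astype(str) == str(chrom)]

    entries: dict[str, dict[int, int]] = {}
    n_ambiguous = 0
    for row in df.itertuples(index=False):
        llr = float(row.log_lik_ratio)
        if llr > llr_threshold:
            call = M
        elif llr < -llr_threshold:
            call = U
        else:
            n_ambiguous += 1
            continue
        offsets = _cg_offsets(str(row.sequence))
        n_motifs = int(row.num_motifs)
        if len(offsets) != n_motifs:
            raise ValueError(
                f"read {row.read_name}: sequence context has {len(offsets)} CG "
                f"motifs but num_motifs={n_motifs}"
            )
        genomic = [int(row.start) + (o - offsets[0]) for o in offsets]
        if tss_strand == "+":
            rels = [g - tss_pos for g in genomic]
        else:
            rels = [tss_pos - g for g in genomic]
        per_read = entries.setdefault(str(row.read_name), {})
        for rel in rels:
            per_read[rel] = call
    if n_ambiguous:
        logger.info("discarded %d ambiguous calls (|LLR| <= %.2f)",
                    n_ambiguous, llr_threshold)

    entries = {rid: calls for rid, calls in entries.items() if calls}
    if not entries:
        raise ValueError("no reads with confident calls overlap the region")
    positions = sorted({rel for calls in entries.values() for rel in calls})
    pos_index = {p: j for j, p in enumerate(positions)}
    read_ids = sorted(entries)
    mat = np.full((len(read_ids), len(positions)), MISSING, dtype=np.int8)
    for i, rid in enumerate(read_ids):
        for rel, call in entries[rid].items():
            mat[i, pos_index[rel]] = call
    return MethylReadMatrix(read_ids, np.asarray(positions), mat, region_label)


def window_unmethylated_counts(
    matrix: MethylReadMatrix,
    window: PromoterWindow,
    min_covered: float = 0.8,
) -> pd.Series:
    """Per-read count of unmethylated CpGs inside the window.

    Reads with non-missing calls at fewer than ``min_covered`` of the
    in-window CpG sites are excluded (and the exclusion logged) to avoid
    truncated-read artifacts.
    """
    in_win = window.contains(matrix.cpg_positions)
    n_sites = int(in_win.sum())
    if n_sites == 0:
        raise ValueError(
            f"no CpG site in window [{window.start_rel}, {window.end_rel}]"
        )
    sub = matrix.calls[:, in_win]
    covered = (sub != MISSING).sum(axis=1)
    keep = covered >= min_covered * n_sites
    if (~keep).any():
        logger.info(
            "excluded %d/%d reads covering < %.0f%% of %d in-window CpGs",
            int((~keep).sum()), matrix.n_reads, 100 * min_covered, n_sites,
        )
    counts = (sub[keep] == U).sum(axis=1)
    ids = [rid for rid, k in zip(matrix.read_ids, keep) if k]
    return pd.Series(counts, index=ids, name="n_unmethylated")


def methylation_percentages(
    matrix: MethylReadMatrix, window: PromoterWindow | None = None
) -> tuple[float, float]:
    """(percent unmethylated, percent methylated) over non-missing calls."""
    calls = matrix.calls
    if window is not None:
        calls = calls[:, window.contains(matrix.cpg_positions)]
    n_u = int((calls == U).sum())
    n_m = int((calls == M).sum())
    total = n_u + n_m
    if total == 0:
        raise ValueError("no non-missing call in region")
    return 100.0 * n_u / total, 100.0 * n_m / total


@dataclass
class BinomialMixtureFit:
    """Two-component binomial mixture over per-read unmethylated counts.

    Component 0 is the *unmethylated* block (higher U-probability).
    """

    weight_unmeth: float
    p_unmeth: float  # U-probability of the unmethylated component
    p_meth: float  # U-probability of the methylated component
    log_likelihood: float
    converged: bool
    bimodal: bool
    n_iter: int


def _em_once(k, n, w0, pa0, pb0, tol, max_iter):
    w, pa, pb = w0, pa0, pb0
    prev = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        la = np.log(w + 1e-300) + stats.binom.logpmf(k, n, pa)
        lb = np.log(1 - w + 1e-300) + stats.binom.logpmf(k, n, pb)
        norm = logsumexp([la, lb], axis=0)
        ll = float(norm.sum())
        ra = np.exp(la - norm)
        w = float(np.mean(ra))
        denom_a = np.sum(ra * n)
        denom_b = np.sum((1 - ra) * n)
        pa = float(np.clip(np.sum(ra * k) / denom_a if denom_a > 0 else 0.5, 1e-6, 1 - 1e-6))
        pb = float(np.clip(np.sum((1 - ra) * k) / denom_b if denom_b > 0 else 0.5, 1e-6, 1 - 1e-6))
        if ll - prev < tol and it > 1:
            return w, pa, pb, ll, True, it
        prev = ll
    return w, pa, pb, prev, False, it


def fit_binomial_mixture(
    counts: Sequence[int],
    n_sites: int | Sequence[int],
    seed: int | None = None,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> BinomialMixtureFit:
    """Fit a 2-component binomial mixture to per-read U counts by EM.

    ``n_sites`` is the number of in-window CpGs (scalar, or per-read when
    coverage varies).  Components are ordered by U-probability (component 0
    = unmethylated block); the fit is flagged bimodal when both weights are
    at least 0.05 and the component probabilities differ by at least 0.5.
    EM restarts from ``n_restarts`` seeded initializations; non-convergence
    across all restarts is flagged and the best fit returned.
    """
    k = np.asarray(list(counts), dtype=float)
    if k.size < 10:
        raise ValueError("need at least 10 reads")
    n = np.broadcast_to(np.asarray(n_sites, dtype=float), k.shape)
    if np.any(k > n):
        raise ValueError("counts exceed n_sites")
    rng = np.random.default_rng(seed)

    best = None
    inits = [(0.5, 0.9, 0.1), (np.mean(k / n), 0.95, 0.05)]
    while len(inits) < n_restarts:
        inits.append(
            (rng.uniform(0.1, 0.9), rng.uniform(0.5, 1.0), rng.uniform(0.0, 0.5))
        )
    for w0, pa0, pb0 in inits[:n_restarts]:
        w0 = float(np.clip(w0, 0.05, 0.95))
        res = _em_once(k, n, w0, pa0, pb0, tol, max_iter)
        if best is None or res[3] > best[3]:
            best = res
    w, pa, pb, ll, conv, it = best
    # order components: unmethylated block = higher U probability
    if pa < pb:
        pa, pb = pb, pa
        w = 1.0 - w
    bimodal = (min(w, 1 - w) >= 0.05) and (pa - pb >= 0.5)
    return BinomialMixtureFit(w, pa, pb, ll, conv, bimodal, it)


def classify_enbloc(
    matrix: MethylReadMatrix,
    window: PromoterWindow,
    tolerance: int = 1,
    min_covered: float = 0.8,
) -> pd.Series:
    """Label each read unmeth_block / meth_block / mixed over the window.

    A read is an unmethylated block when it carries at most ``tolerance``
    methylated calls in the window, a methylated block when it carries at
    most ``tolerance`` unmethylated calls, and mixed otherwise.  Reads
    covering fewer than ``min_covered`` of the in-window sites are excluded.
    """
    in_win = window.contains(matrix.cpg_positions)
    n_sites = int(in_win.sum())
    if n_sites == 0:
        raise ValueError("no CpG site in window")
    sub = matrix.calls[:, in_win]
    covered = (sub != MISSING).sum(axis=1)
    keep = covered >= min_covered * n_sites
    n_m = (sub == M).sum(axis=1)
    n_u = (sub == U).sum(axis=1)
    labels = np.where(
        n_m <= tolerance, "unmeth_block", np.where(n_u <= tolerance, "meth_block", "mixed")
    )
    ids = [rid for rid, kp in zip(matrix.read_ids, keep) if kp]
    return pd.Series(labels[keep], index=ids, name="block_label")
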