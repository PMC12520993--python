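"""Screen deconvolution: FASTQ reads -> counts tables and editing summaries.

The sequencing layout amplifies the protospacer, 3' extension and sensor in
separate reads of the same cluster, so a sample is declared as three
parallel FASTQ files (roles ``spacer``, ``extension``, ``sensor``).  Reads
whose mean Phred across the declared regions is below 30 are dropped.  A
cluster is assigned to a design only when spacer and extension match the
same design exactly; a spacer and extension from different designs is a
lentiviral recombination event.  Sensor outcomes are called after a 5-nt
barcode check, inside a quantification window that excludes both barcodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import edlib
import numpy as np
import pandas as pd
import pysam

RECOMBINED = "RECOMBINED"
UNMATCHED = "UNMATCHED"

CORRECT = "CORRECT"
UNEDITED = "UNEDITED"
INDEL = "INDEL"
OTHER = "OTHER"
SENSOR_RECOMBINED = "SENSOR_RECOMBINED"
AMBIGUOUS_BARCODE = "AMBIGUOUS_BARCODE"

MIN_READS_EFFICIENCY = 100  # report editing efficiency
MIN_READS_CALIBRATION = 10  # use a sensor for screen calibration


@dataclass
class ReadRecord:
    sample_id: str
    spacer_seq: str
    extension_seq: str
    sensor_seq: str
    mean_phred: float


@dataclass
class SensorRefs:
    wt_window: str
    edited_window: str
    barcode5: str
    barcode3: str
    collision: bool


class LibraryIndex:
    """Exact-match lookup structures built from a library manifest."""

    def __init__(self, manifest: pd.DataFrame):
        self.spacer_to_ids: dict[str, set] = {}
        self.ext_to_ids: dict[str, set] = {}
        self.sensors: dict[str, SensorRefs] = {}
        self.barcode_pairs: set[tuple] = set()
        self.variant_of: dict[str, str] = {}
        for row in manifest.itertuples(index=False):
            did = row.design_id
            self.spacer_to_ids.setdefault(row.spacer_oligo, set()).add(did)
            self.ext_to_ids.setdefault(row.extension, set()).add(did)
            self.variant_of[did] = row.variant_id
            wt, ed = row.wt_sensor, row.edited_sensor
            collision = bool(row.barcode_collision)
            self.sensors[did] = SensorRefs(
                wt_window=wt[5:-5],
                edited_window=ed[5:-5],
                barcode5=row.barcode5,
                barcode3=row.barcode3,
                collision=collision,
            )
            self.barcode_pairs.add((row.barcode5, row.barcode3))


def _mean_phred(quals: list[str]) -> float:
    arr = np.frombuffer("".join(quals).encode(), dtype=np.uint8)
    return float(arr.mean()) - 33.0 if arr.size else 0.0


def parse_reads(
    fastq_paths: dict,
    sample_id: str,
    min_mean_phred: float = 30.0,
    counters: Optional[dict] = None,
) -> Iterator[ReadRecord]:
    """Stream quality-filtered reads from a sample's parallel FASTQ files.

    ``fastq_paths`` maps the roles ``spacer``/``extension``/``sensor`` to
    file paths (plain or gzipped).  Low-quality clusters (mean Phred over
    all three regions below the threshold) are counted and skipped.
    """
    counters = counters if counters is not None else {}
    counters.setdefault("total", 0)
    counters.setdefault("low_quality", 0)
    handles = {
        role: pysam.FastxFile(str(path)) for role, path in fastq_paths.items()
    }
    try:
        for sp, ex, se in zip(
            handles["spacer"], handles["extension"], handles["sensor"]
        ):
            counters["total"] += 1
            mean_q = _mean_phred(
                [sp.quality or "", ex.quality or "", se.quality or ""]
            )
            if mean_q < min_mean_phred:
                counters["low_quality"] += 1
                continue
            yield ReadRecord(
                sample_id=sample_id,
                spacer_seq=sp.sequence.upper(),
                extension_seq=ex.sequence.upper(),
                sensor_seq=se.sequence.upper(),
                mean_phred=mean_q,
            )
    finally:
        for fh in handles.values():
            fh.close()


def _one_mismatch_hits(seq: str, table: dict) -> set:
    hits = set()
    for i in range(len(seq)):
        for base in "ACGT":
            if base == seq[i]:
                continue
            ids = table.get(seq[:i] + base + seq[i + 1 :])
            if ids:
                hits |= ids
    return hits


def assign_pegrna(
    record: ReadRecord, index: LibraryIndex, rescue_one_mismatch: bool = False
) -> str:
    """Design id for a read, or RECOMBINED / UNMATCHED.

    Exact matching of both spacer and extension by default; the optional
    unique-one-mismatch rescue applies only when the rescued region maps to
    exactly one design set.
    """
    ids_s = index.spacer_to_ids.get(record.spacer_seq)
    ids_e = index.ext_to_ids.get(record.extension_seq)
    if rescue_one_mismatch:
        if not ids_s:
            hits = _one_mismatch_hits(record.spacer_seq, index.spacer_to_ids)
            ids_s = hits or None
        if not ids_e:
            hits = _one_mismatch_hits(record.extension_seq, index.ext_to_ids)
            ids_e = hits if len(hits) == 1 else None
    if not ids_s or not ids_e:
        return UNMATCHED
    common = ids_s & ids_e
    if not common:
        return RECOMBINED
    return min(common)


def classify_sensor(record: ReadRecord, refs: SensorRefs, index: LibraryIndex) -> str:
    """Outcome of one sensor read against its assigned design.

    Barcode check first: the design's own barcodes proceed to window
    classification; another design's barcode pair is a sensor-level
    recombination event (discarded from editing fractions); unknown
    barcodes are retained as candidate indels.  The quantification window
    (read minus 5-nt flanks) is then compared with the edited and WT
    references; a length change relative to both, or an optimal alignment
    strictly cheaper than substitutions-only, is an INDEL; remaining
    substitution-only mismatches are OTHER.
    """
    if refs.collision:
        return AMBIGUOUS_BARCODE
    s = record.sensor_seq
    if len(s) <= 10:
        return OTHER
    pair = (s[:5], s[-5:])
    if pair != (refs.barcode5, refs.barcode3) and pair in index.barcode_pairs:
        return SENSOR_RECOMBINED
    window = s[5:-5]
    if window == refs.edited_window:
        return CORRECT
    if window == refs.wt_window:
        return UNEDITED
    lengths = {len(refs.wt_window), len(refs.edited_window)}
    if len(window) not in lengths:
        return INDEL
    for ref in (refs.wt_window, refs.edited_window):
        if len(ref) != len(window):
            continue
        hamming = sum(a != b for a, b in zip(window, ref))
        dist = edlib.align(window, ref, mode="NW", task="distance")["editDistance"]
        if dist >= hamming:
            return OTHER
    return INDEL


def tabulate(
    stream: Iterator[ReadRecord],
    index: LibraryIndex,
    counters: Optional[dict] = None,
    rescue_one_mismatch: bool = False,
) -> tuple[pd.Series, pd.DataFrame]:
    """Aggregate one sample's reads into counts and editing summaries.

    Returns ``(counts, summary)`` where ``counts`` is a Series of assigned
    reads per design and ``summary`` one row per design with sensor outcome
    counts, outcome fractions and threshold flags (fewer than 100 reads for
    efficiency reporting, fewer than 10 for calibration).
    """
    counters = counters if counters is not None else {}
    for key in ("assigned", "recombined", "unmatched", "sensor_recombined"):
        counters.setdefault(key, 0)
    counts: dict[str, int] = {}
    outcomes: dict[str, dict] = {}
    sample_id = None
    for record in stream:
        sample_id = record.sample_id
        assignment = assign_pegrna(record, index, rescue_one_mismatch)
        if assignment == UNMATCHED:
            counters["unmatched"] += 1
            continue
        if assignment == RECOMBINED:
            counters["recombined"] += 1
            continue
        counters["assigned"] += 1
        counts[assignment] = counts.get(assignment, 0) + 1
        outcome = classify_sensor(record, index.sensors[assignment], index)
        if outcome == SENSOR_RECOMBINED:
            counters["sensor_recombined"] += 1
            continue
        if outcome == AMBIGUOUS_BARCODE:
            continue
        per = outcomes.setdefault(
            assignment, {CORRECT: 0, UNEDITED: 0, INDEL: 0, OTHER: 0}
        )
        per[outcome] += 1

    rows = []
    for did in sorted(index.sensors):
        per = outcomes.get(did, {CORRECT: 0, UNEDITED: 0, INDEL: 0, OTHER: 0})
        n = sum(per.values())
        rows.append(
            {
                "design_id": did,
                "sample_id": sample_id,
                "n_assigned_reads": counts.get(did, 0),
                "n_sensor_reads": n,
                "n_correct": per[CORRECT],
                "n_unedited": per[UNEDITED],
                "n_indel": per[INDEL],
                "n_other": per[OTHER],
                "frac_correct": per[CORRECT] / n if n else 0.0,
                "frac_unedited": per[UNEDITED] / n if n else 0.0,
                "frac_indel": per[INDEL] / n if n else 0.0,
                "frac_other": per[OTHER] / n if n else 0.0,
                "below_efficiency_min": n < MIN_READS_EFFICIENCY,
                "below_calibration_min": n < MIN_READS_CALIBRATION,
            }
        )
    summary = pd.DataFrame(rows)
    summary["correct_pct"] = 100.0 * summary["frac_correct"]
    counts_series = pd.Series(counts, dtype=int).reindex(
        sorted(index.sensors), fill_value=0
    )
    return counts_series, summary


def background_subtract(
    summary: pd.DataFrame, plasmid_summary: pd.DataFrame | None
) -> pd.DataFrame:
    """Add the background-subtracted correct editing percentage.

    Subtracts each design's plasmid-library correct % from its timepoint
    correct %, floored at 0.  Designs missing from the plasmid summary get
    a subtraction of 0 and a flag.
    """
    out = summary.copy()
    if plasmid_summary is None:
        out["correct_pct_bg_subtracted"] = out["correct_pct"]
        out["plasmid_missing"] = True
        return out
    plasmid = plasmid_summary.set_index("design_id")["correct_pct"]
    background = out["design_id"].map(plasmid)
    out["plasmid_missing"] = background.isna()
    out["correct_pct_bg_subtracted"] = (
        out["correct_pct"] - background.fillna(0.0)
    ).clip(lower=0.0)
    return out


def run_deconvolution(
    samples: dict,
    manifest: pd.DataFrame,
    min_mean_phred: float = 30.0,
    rescue_one_mismatch: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Deconvolve a whole screen.

    ``samples`` maps sample ids to role->FASTQ-path dicts.  Returns the
    design x sample counts table, the concatenated editing summaries and a
    per-sample category tally (total = assigned + recombined + unmatched +
    low_quality).
    """
    index = LibraryIndex(manifest)
    columns = {}
    summaries = []
    tallies = []
    for sample_id, paths in samples.items():
        counters: dict[str, int] = {}
        stream = parse_reads(paths, sample_id, min_mean_phred, counters)
        counts, summary = tabulate(stream, index, counters, rescue_one_mismatch)
        summary["sample_id"] = sample_id
        columns[sample_id] = counts
        summaries.append(summary)
        tallies.append({"sample_id": sample_id, **counters})
    counts_table = pd.DataFrame(columns)
    counts_table.index.name = "design_id"
    return counts_table, pd.concat(summaries, ignore_index=True), pd.DataFrame(tallies)
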