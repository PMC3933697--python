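"""Readers/writers for the pipeline's file formats and the pipeline driver.

Formats: FASTA for IDR sequences (record id = IDR id), PSI-BLAST ASCII
PSSMs (the ``-out_ascii_pssm`` dialect, one file per IDR named
``<idr_id>.pssm``), and headered TSV for annotations, the term parent map,
feature matrices and all result tables. Readers reject malformed records
with file/line context; every dropped or altered datum is logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import classify, evaluate, features
from .features import ALPHABET, IDRSequence, PSSMatrix, sanitize_sequence

logger = logging.getLogger("idrfunc")

#: PSI-BLAST prints matrix columns in this (non-alphabetical) order
PSIBLAST_COLUMN_ORDER = "ARNDCQEGHILKMFPSTWYV"


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[IDRSequence]:
    """Read IDR sequences; ids must be unique; non-standard residues dropped.

    The protein id is taken from a ``protein=<id>`` token in the FASTA
    description when present, else from the id prefix before ``_IDR``.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    seen: set[str] = set()
    out: list[IDRSequence] = []
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        clean, dropped = sanitize_sequence(str(rec.seq))
        if dropped:
            logger.warning("%s: record %s: dropped %d non-standard residues", path, rec.id, dropped)
        if not clean:
            raise FormatError(f"{path}: record {rec.id!r} empty after sanitization")
        protein_id = rec.id.split("_IDR")[0]
        for token in rec.description.split():
            if token.startswith("protein="):
                protein_id = token.split("=", 1)[1]
        out.append(IDRSequence(idr_id=rec.id, protein_id=protein_id, residues=clean))
    return out


def write_fasta(sequences: Sequence[IDRSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.idr_id, description=f"protein={s.protein_id}")
        for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------


def read_pssm_ascii(
    path: str | Path, mode: Literal["percentages", "logodds_sigmoid"] = "percentages"
) -> PSSMatrix:
    """Parse one ``-out_ascii_pssm`` file into row-normalized probabilities.

    The 40-letter header line fixes the column order (PSI-BLAST uses
    ARNDC..., not alphabetical); columns are mapped to the canonical
    alphabet. ``mode='percentages'`` divides the weighted-observed
    percentage block by 100 and renormalizes each row;
    ``mode='logodds_sigmoid'`` squashes the log-odds block through
    1/(1+e^-x) and normalizes. All-zero rows become uniform with a warning.
    """
    path = Path(path)
    if mode not in ("percentages", "logodds_sigmoid"):
        raise ValueError(f"unknown pssm mode {mode!r}")
    lines = path.read_text().splitlines()

    col_letters: list[str] | None = None
    rows: list[np.ndarray] = []
    expected_pos = 1
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if col_letters is None:
            if len(tokens) == 40 and all(t in ALPHABET and len(t) == 1 for t in tokens):
                col_letters = tokens
            continue
        if not tokens:
            break  # blank line ends the matrix block
        if not tokens[0].lstrip("-").isdigit():
            break  # footer (K, Lambda) lines
        if len(tokens) < 42 or len(tokens[1]) != 1:
            raise FormatError(f"{path}:{lineno}: expected 'pos aa' + 40 matrix columns, got {len(tokens)} tokens")
        if int(tokens[0]) != expected_pos:
            raise FormatError(f"{path}:{lineno}: position {tokens[0]} out of order (expected {expected_pos})")
        expected_pos += 1
        try:
            numbers = [float(t) for t in tokens[2:42]]
        except ValueError as e:
            raise FormatError(f"{path}:{lineno}: non-numeric matrix entry ({e})") from None
        rows.append(np.array(numbers))
    if col_letters is None:
        raise FormatError(f"{path}: no 40-letter PSSM header line found")
    if not rows:
        raise FormatError(f"{path}: no matrix rows found")

    mat = np.vstack(rows)
    logodds, percents = mat[:, :20], mat[:, 20:40]
    lo_order, pc_order = col_letters[:20], col_letters[20:]
    if mode == "percentages":
        raw = percents / 100.0
        order = pc_order
    else:
        raw = 1.0 / (1.0 + np.exp(-logodds))
        order = lo_order
    # map file columns to canonical alphabet order
    perm = [order.index(a) for a in ALPHABET]
    raw = raw[:, perm]

    sums = raw.sum(axis=1)
    zero = sums <= 0
    if np.any(zero):
        logger.warning("%s: %d all-zero rows replaced by uniform", path, int(zero.sum()))
        raw[zero] = 1.0 / 20.0
        sums = raw.sum(axis=1)
    probs = raw / sums[:, None]
    return PSSMatrix(idr_id=path.stem, probs=probs)


def write_pssm_ascii(pssm: PSSMatrix, seq: IDRSequence, path: str | Path) -> None:
    """Write the PSI-BLAST ASCII dialect (percentages to 4 decimals).

    The log-odds block holds rounded half-bit scores against the overall
    column mean; the percentage block carries the probabilities.
    """
    if pssm.length != seq.length:
        raise ValueError(f"PSSM rows ({pssm.length}) != sequence length ({seq.length})")
    perm = [ALPHABET.index(a) for a in PSIBLAST_COLUMN_ORDER]
    probs = pssm.probs[:, perm]
    bg = np.maximum(probs.mean(axis=0), 1e-4)
    logodds = np.round(2.0 * np.log2(np.maximum(probs, 1e-4) / bg)).astype(int)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed percentages rounded down, information per position, and relative weight of gapless real matches to pseudocounts",
        "            " + "   ".join(PSIBLAST_COLUMN_ORDER) + "   " + "   ".join(PSIBLAST_COLUMN_ORDER),
    ]
    for i, residue in enumerate(seq.residues):
        lo = " ".join(f"{v:4d}" for v in logodds[i])
        pc = " ".join(f"{100 * v:8.4f}" for v in probs[i])
        lines.append(f"{i + 1:5d} {residue} {lo}  {pc}  0.00 0.00")
    lines += ["", "                      K         Lambda", "Standard Ungapped    0.1337     0.3176", ""]
    Path(path).write_text("\n".join(lines))


def read_pssm_dir(
    pssm_dir: str | Path,
    idr_ids: Sequence[str],
    mode: Literal["percentages", "logodds_sigmoid"] = "percentages",
) -> dict[str, PSSMatrix]:
    """Load ``<idr_id>.pssm`` for each id; missing files are counted, not fatal."""
    pssm_dir = Path(pssm_dir)
    out: dict[str, PSSMatrix] = {}
    missing = 0
    for idr_id in idr_ids:
        p = pssm_dir / f"{idr_id}.pssm"
        if not p.exists():
            missing += 1
            continue
        out[idr_id] = read_pssm_ascii(p, mode=mode)
    if missing:
        logger.warning("%s: %d of %d IDRs have no PSSM file", pssm_dir, missing, len(idr_ids))
    return out


# ---------------------------------------------------------------------------
# annotation / parent-map TSV
# ---------------------------------------------------------------------------


def read_parent_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("child_id", "parent_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return dict(zip(df["child_id"], df["parent_id"]))


def write_parent_map(parent_map: Mapping[str, str], path: str | Path) -> None:
    df = pd.DataFrame(sorted(parent_map.items()), columns=["child_id", "parent_id"])
    df.to_csv(path, sep="\t", index=False)


def read_annotations(
    path: str | Path, parent_map: Mapping[str, str] | None = None
) -> list[classify.TermAnnotation]:
    """Read the IDR annotation table (idr_id, protein_id, terms).

    ``terms`` is a comma-separated GO Slim id list. IDRs sharing a
    protein_id are joined to the union of their term sets (every IDR
    carries its protein's full annotation). Terms absent from the parent
    map's vocabulary are logged and retained.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("idr_id", "protein_id", "terms"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    by_protein: dict[str, set[str]] = {}
    rows: list[tuple[str, str]] = []
    for r in df.itertuples(index=False):
        terms = {t for t in r.terms.split(",") if t}
        by_protein.setdefault(r.protein_id, set()).update(terms)
        rows.append((r.idr_id, r.protein_id))
    if parent_map is not None:
        vocab = set(parent_map) | set(parent_map.values())
        unknown = set().union(*by_protein.values()) - vocab if by_protein else set()
        if unknown:
            logger.warning("%s: %d terms not in parent-map vocabulary (retained)", path, len(unknown))
    return [
        classify.TermAnnotation(idr_id=i, protein_id=p, terms=frozenset(by_protein[p]))
        for i, p in rows
    ]


def write_annotations(
    annotations: Mapping[str, frozenset[str]], protein_of: Mapping[str, str], path: str | Path
) -> None:
    rows = [
        {"idr_id": idr, "protein_id": protein_of[idr], "terms": ",".join(sorted(annotations[idr]))}
        for idr in sorted(annotations)
    ]
    pd.DataFrame(rows, columns=["idr_id", "protein_id", "terms"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# feature matrix TSV
# ---------------------------------------------------------------------------


def write_feature_matrix(
    idr_ids: Sequence[str], X: np.ndarray, component_names: Sequence[str], path: str | Path
) -> None:
    df = pd.DataFrame(X, columns=list(component_names))
    df.insert(0, "idr_id", list(idr_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_feature_matrix(path: str | Path) -> tuple[list[str], np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t")
    if "idr_id" not in df.columns:
        raise FormatError(f"{path}: missing idr_id column")
    ids = df["idr_id"].astype(str).tolist()
    names = tuple(c for c in df.columns if c != "idr_id")
    return ids, df[list(names)].to_numpy(dtype=float), names


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Paths and options of one end-to-end run (defaults are the protocol)."""

    fasta: Path
    annotations: Path
    parent_map: Path
    out_dir: Path
    pssm_dir: Path | None = None
    families: tuple[str, ...] = features.ALL_FAMILIES
    pssm_mode: Literal["percentages", "logodds_sigmoid"] = "percentages"
    k: int = 10
    min_positives: int = classify.MIN_POSITIVES
    seed: int = 0
    test_n: int = 105
    prob_grid: tuple[float, ...] = evaluate.DEFAULT_PROB_GRID
    run_pr: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.test_n < 1:
            raise ValueError("test_n must be >= 1")
        if any(not 0.0 <= p <= 1.0 for p in self.prob_grid):
            raise ValueError("prob_grid values must lie in [0, 1]")


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """features -> classify -> evaluate for each configured family.

    Writes per-family feature matrices, the CV confusion table, the
    per-term metrics table, the per-family averages (Table-2 shape) and —
    when ``run_pr`` — the per-IDR precision-recall curve over a held-out
    test set of ``test_n`` IDRs. Deterministic for a fixed seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sequences = read_fasta(config.fasta)
    parent_map = read_parent_map(config.parent_map)
    raw = read_annotations(config.annotations, parent_map)
    expanded = classify.expand_all(raw, parent_map)
    ann = {a.idr_id: a.terms for a in expanded}
    missing_ann = [s.idr_id for s in sequences if s.idr_id not in ann]
    if missing_ann:
        raise FormatError(f"{len(missing_ann)} IDRs lack annotation rows (e.g. {missing_ann[0]!r})")
    terms = sorted(set().union(*ann.values())) if ann else []

    pssms: dict[str, PSSMatrix] = {}
    fams = tuple(config.families)
    if "profile_bigrams" in fams:
        if config.pssm_dir is None:
            logger.warning("profile_bigrams requested but no pssm_dir given; family dropped")
            fams = tuple(f for f in fams if f != "profile_bigrams")
        else:
            pssms = read_pssm_dir(config.pssm_dir, [s.idr_id for s in sequences], config.pssm_mode)

    confusion_tables = []
    metric_tables = []
    averages_rows = []
    pr_tables = []
    skipped_rows = []
    for family in fams:
        ids, X, names = features.feature_matrix(family, sequences, pssms)
        write_feature_matrix(ids, X, names, out / f"features_{family}.tsv")

        conf, skipped = classify.cross_validate_dataset(
            ids, X, ann, terms, family, k=config.k, seed=config.seed,
            min_positives=config.min_positives,
        )
        confusion_tables.append(conf)
        skipped_rows += [{"family": family, "term_id": t, "reason": r} for t, r in skipped]

        term_metrics = [
            evaluate.confusion_metrics(
                evaluate.ConfusionCounts(tp=r.tp, fp=r.fp, tn=r.tn, fn=r.fn), r.term_id, family
            )
            for r in conf.itertuples(index=False)
        ]
        metric_tables.append(evaluate.metrics_table(term_metrics))
        if term_metrics:
            avg = evaluate.average_over_terms(term_metrics)
            avg["family"] = family
            avg["n_skipped"] = float(len(skipped))
            averages_rows.append(avg)

        if config.run_pr:
            pr_tables.append(_pr_for_family(family, ids, X, ann, terms, config))

    results = {
        "confusion": pd.concat(confusion_tables, ignore_index=True) if confusion_tables else pd.DataFrame(),
        "metrics": pd.concat(metric_tables, ignore_index=True) if metric_tables else pd.DataFrame(),
        "averages": pd.DataFrame(averages_rows, columns=["family", "n_terms", "sensitivity", "specificity", "precision", "mcc", "n_skipped"]),
        "skipped": pd.DataFrame(skipped_rows, columns=["family", "term_id", "reason"]),
    }
    if config.run_pr:
        results["pr_curve"] = pd.concat(pr_tables, ignore_index=True) if pr_tables else pd.DataFrame()

    results["confusion"].to_csv(out / "confusion.tsv", sep="\t", index=False)
    results["metrics"].to_csv(out / "metrics.tsv", sep="\t", index=False, float_format="%.10g")
    results["averages"].to_csv(out / "averages.tsv", sep="\t", index=False, float_format="%.10g")
    results["skipped"].to_csv(out / "skipped.tsv", sep="\t", index=False)
    if config.run_pr:
        results["pr_curve"].to_csv(out / "pr_curve.tsv", sep="\t", index=False, float_format="%.10g")
    return results


def _pr_for_family(
    family: str,
    ids: Sequence[str],
    X: np.ndarray,
    ann: Mapping[str, frozenset[str]],
    terms: Sequence[str],
    config: PipelineConfig,
) -> pd.DataFrame:
    """105-IDR held-out protocol: train on the rest, sweep the threshold."""
    test_ids, train_ids = evaluate.sample_test_set(list(ids), n=config.test_n, seed=config.seed)
    idx = {r: i for i, r in enumerate(ids)}
    tr = np.array([idx[r] for r in train_ids])
    te = np.array([idx[r] for r in test_ids])

    pred_rows = []
    trained_terms = []
    for term in terms:
        y_tr = classify.binarize(ann, train_ids, term)
        try:
            probs = classify.train_and_score(
                X[tr], y_tr, X[te], term, family, min_positives=config.min_positives
            )
        except classify.TermSkipped as e:
            logger.info("PR: %s", e)
            continue
        trained_terms.append(term)
        pred_rows += [
            {"idr_id": r, "term_id": term, "probability": float(p)} for r, p in zip(test_ids, probs)
        ]
    predictions = pd.DataFrame(pred_rows, columns=["idr_id", "term_id", "probability"])
    trained = set(trained_terms)
    known = {r: set(ann[r]) & trained for r in test_ids}
    curve = evaluate.pr_analysis(predictions, known, prob_grid=config.prob_grid, family=family)
    pts = curve.points.copy()
    pts.insert(0, "family", family)
    return pts
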