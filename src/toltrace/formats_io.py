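"""Readers, writers and shared domain types for the pipeline.

All genomic coordinates are 1-based inclusive (GFF3 convention); residue
coordinates are likewise 1-based inclusive.  Gene rank is the 0-based ordinal
of a gene along its replicon after sorting by start coordinate, regardless of
strand — proximity throughout the pipeline is strand-agnostic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
import pandas as pd
from Bio import SearchIO, SeqIO


class ParseError(ValueError):
    """Malformed input file (names the offending line where possible)."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene with genomic coordinates and optional protein."""

    gene_id: str
    genome_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    rank: int = 0
    product: str = ""
    protein_length: int = 0
    protein_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(
                f"gene {self.gene_id}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.protein_seq is not None:
            object.__setattr__(self, "protein_length", len(self.protein_seq))


@dataclass(frozen=True)
class DomainHit:
    """A single Pfam domain hit on a protein (envelope coordinates)."""

    gene_id: str
    pfam_acc: str
    bitscore: float
    evalue: float
    env_start: int
    env_end: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError(
                f"hit {self.gene_id}/{self.pfam_acc}: negative E-value {self.evalue}"
            )
        if self.env_start > self.env_end:
            raise ValidationError(
                f"hit {self.gene_id}/{self.pfam_acc}: env_start > env_end"
            )


@dataclass
class SecondaryStructureProfile:
    """Three-state secondary structure plus optional per-residue annotations.

    ``states`` is one character per residue over {H, E, C}; ``confidence``
    holds the winning state's confidence in [0, 1].  ``tmh_span`` is a
    1-based inclusive residue interval; ``ppii_scores`` are per-residue
    polyproline-II propensities; ``signal_call`` is an external secretion /
    lipidation prediction.
    """

    gene_id: str
    states: str
    confidence: list[float] = field(default_factory=list)
    tmh_span: Optional[tuple[int, int]] = None
    ppii_scores: Optional[list[float]] = None
    signal_call: Optional[str] = None  # none | sec_signal | lipoprotein

    def __post_init__(self) -> None:
        bad = set(self.states) - {"H", "E", "C"}
        if bad:
            raise ValidationError(f"{self.gene_id}: invalid SS states {sorted(bad)}")
        if self.confidence and len(self.confidence) != len(self.states):
            raise ValidationError(f"{self.gene_id}: confidence length mismatch")
        if self.tmh_span is not None:
            s, e = self.tmh_span
            if not (1 <= s <= e <= len(self.states)):
                raise ValidationError(
                    f"{self.gene_id}: TMH span {self.tmh_span} outside "
                    f"[1, {len(self.states)}]"
                )

    def __len__(self) -> int:
        return len(self.states)


# ---------------------------------------------------------------------------
# Gene tables
# ---------------------------------------------------------------------------

_GENE_TSV_COLUMNS = [
    "gene_id", "genome_id", "replicon_id", "start", "end",
    "strand", "rank", "product", "protein_length", "protein_seq",
]


def _assign_ranks(records: list[GeneRecord]) -> list[GeneRecord]:
    """Sort by (replicon_id, start) and assign 0-based rank per replicon."""
    records = sorted(records, key=lambda g: (g.replicon_id, g.start, g.gene_id))
    out: list[GeneRecord] = []
    counters: dict[str, int] = {}
    for g in records:
        r = counters.get(g.replicon_id, 0)
        counters[g.replicon_id] = r + 1
        out.append(dataclasses.replace(g, rank=r))
    return out


def _check_unique_ids(records: Iterable[GeneRecord]) -> None:
    seen: set[str] = set()
    for g in records:
        if g.gene_id in seen:
            raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)


def read_gene_table(
    path: str | Path,
    dialect: str = "gff3",
    genome_id: Optional[str] = None,
    feature_types: Sequence[str] = ("CDS", "gene"),
) -> list[GeneRecord]:
    """Read an annotated gene table as a rank-sorted list of GeneRecords.

    ``dialect`` is ``gff3`` (parsed with gffutils; the first feature type in
    ``feature_types`` that occurs in the file is used) or ``tsv`` (the
    pipeline's own tabular layout).  ``genome_id`` defaults to the file stem.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    if dialect == "gff3":
        records = _read_gff3(path, genome_id, feature_types)
    elif dialect == "tsv":
        records = _read_gene_tsv(path)
    else:
        raise ValueError(f"unknown gene-table dialect {dialect!r}")
    _check_unique_ids(records)
    return _assign_ranks(records)


def _read_gff3(path: Path, genome_id: str, feature_types: Sequence[str]) -> list[GeneRecord]:
    if path.stat().st_size == 0:
        return []
    # pre-validate coordinates so errors can name the line
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if end < start:
                raise ParseError(f"{path}:{lineno}: end ({end}) < start ({start})")
    try:
        db = gffutils.create_db(
            str(path), ":memory:", id_spec="ID", merge_strategy="error",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises several internal error types
        raise ParseError(f"{path}: GFF3 parse failed: {exc}") from exc
    present = {f.featuretype for f in db.all_features()}
    ftype = next((t for t in feature_types if t in present), None)
    if ftype is None:
        return []
    records = []
    for feat in db.features_of_type(ftype):
        product = (feat.attributes.get("product") or [""])[0]
        records.append(GeneRecord(
            gene_id=feat.id,
            genome_id=genome_id,
            replicon_id=feat.seqid,
            start=feat.start,
            end=feat.end,
            strand=feat.strand if feat.strand in ("+", "-") else "+",
            product=product,
        ))
    return records


def _read_gene_tsv(path: Path) -> list[GeneRecord]:
    if path.stat().st_size == 0:
        return []
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_GENE_TSV_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), 2):
        try:
            start, end = int(row.start), int(row.end)
        except ValueError:
            raise ParseError(f"{path}: line {i}: non-integer coordinates") from None
        if end < start:
            raise ParseError(f"{path}: line {i}: end ({end}) < start ({start})")
        seq = getattr(row, "protein_seq", "") or None
        records.append(GeneRecord(
            gene_id=row.gene_id,
            genome_id=row.genome_id,
            replicon_id=row.replicon_id,
            start=start,
            end=end,
            strand=row.strand,
            product=getattr(row, "product", ""),
            protein_length=int(getattr(row, "protein_length", 0) or (len(seq) if seq else 0)),
            protein_seq=seq,
        ))
    return records


def attach_sequences(
    genes: Sequence[GeneRecord], fasta_path: str | Path
) -> list[GeneRecord]:
    """Attach protein sequences from a FASTA keyed by gene_id."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    out = []
    for g in genes:
        s = seqs.get(g.gene_id)
        if s is not None:
            g = dataclasses.replace(g, protein_seq=s, protein_length=len(s))
        out.append(g)
    return out


# ---------------------------------------------------------------------------
# HMMER per-domain tabular output
# ---------------------------------------------------------------------------

def read_domain_hits(path: str | Path) -> list[DomainHit]:
    """Parse hmmscan per-domain tabular output into DomainHits.

    The query is the protein (gene_id), the target the Pfam model; the Pfam
    accession version suffix is stripped.  Envelope coordinates are converted
    to 1-based inclusive.  Comment lines are skipped.
    """
    path = Path(path)
    # Reject rows with too few columns up front: SearchIO silently mis-parses them.
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            if len(line.split()) < 23:
                raise ParseError(
                    f"{path}:{lineno}: expected >=23 whitespace-separated columns"
                )
    hits: list[DomainHit] = []
    try:
        results = list(SearchIO.parse(str(path), "hmmscan3-domtab"))
    except Exception as exc:
        raise ParseError(f"{path}: domtblout parse failed: {exc}") from exc
    for qresult in results:
        for hit in qresult:
            acc = hit.accession.split(".")[0]
            for hsp in hit:
                hits.append(DomainHit(
                    gene_id=qresult.id,
                    pfam_acc=acc,
                    bitscore=float(hsp.bitscore),
                    evalue=float(hsp.evalue),
                    env_start=hsp.env_start + 1,  # 0-based half-open -> 1-based incl.
                    env_end=hsp.env_end,
                ))
    return hits


_DOMTAB_HEADER = (
    "# target name        accession   tlen query name           accession   qlen"
    "   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to"
    "  from    to  from    to  acc description of target\n"
)


def write_domain_hits(
    hits: Sequence[DomainHit],
    path: str | Path,
    protein_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Write DomainHits as hmmscan per-domain tabular output (round-trippable)."""
    protein_lengths = protein_lengths or {}
    with open(path, "w") as fh:
        fh.write(_DOMTAB_HEADER)
        for h in hits:
            qlen = protein_lengths.get(h.gene_id, h.env_end)
            fh.write(
                f"{h.pfam_acc:<20} {h.pfam_acc:<10} {h.env_end - h.env_start + 1:>5} "
                f"{h.gene_id:<20} {'-':<10} {qlen:>5} "
                f"{h.evalue:>9.3g} {h.bitscore:>6.1f} {0.0:>5.1f} "
                f"{1:>3} {1:>3} {h.evalue:>9.3g} {h.evalue:>9.3g} "
                f"{h.bitscore:>6.1f} {0.0:>5.1f} "
                f"{1:>5} {h.env_end - h.env_start + 1:>5} "
                f"{h.env_start:>5} {h.env_end:>5} "
                f"{h.env_start:>5} {h.env_end:>5} 0.99 -\n"
            )


# ---------------------------------------------------------------------------
# Secondary-structure dialects
# ---------------------------------------------------------------------------

_STATE_PRECEDENCE = {"H": 0, "E": 1, "C": 2}  # tie-break order H > E > C


def _pick_state(conf_h: float, conf_e: float, conf_c: float) -> tuple[str, float]:
    ranked = sorted(
        [("H", conf_h), ("E", conf_e), ("C", conf_c)],
        key=lambda sc: (-sc[1], _STATE_PRECEDENCE[sc[0]]),
    )
    return ranked[0]


def read_ss_profile(
    path: str | Path,
    dialect: str = "ss2",
    gene_id: Optional[str] = None,
    expected_length: Optional[int] = None,
) -> SecondaryStructureProfile:
    """Read a PSIPRED-style secondary-structure prediction.

    ``ss2`` rows carry per-state confidences; the state is re-derived as the
    maximum-confidence state with ties broken by the fixed precedence H>E>C.
    ``horiz`` carries a single 0-9 confidence digit per residue (scaled /9).
    """
    path = Path(path)
    if gene_id is None:
        gene_id = path.stem
    if dialect == "ss2":
        states, confs = _read_ss2(path)
    elif dialect == "horiz":
        states, confs = _read_horiz(path)
    else:
        raise ValueError(f"unknown SS dialect {dialect!r}")
    if expected_length is not None and len(states) != expected_length:
        raise ParseError(
            f"{path}: {len(states)} residues parsed, {expected_length} expected"
        )
    return SecondaryStructureProfile(gene_id=gene_id, states=states, confidence=confs)


def _read_ss2(path: Path) -> tuple[str, list[float]]:
    states: list[str] = []
    confs: list[float] = []
    expected_idx = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns, got {len(cols)}")
            idx = int(cols[0])
            if idx != expected_idx:
                raise ParseError(
                    f"{path}:{lineno}: residue index {idx}, expected {expected_idx}"
                )
            expected_idx += 1
            conf_c, conf_h, conf_e = float(cols[3]), float(cols[4]), float(cols[5])
            state, conf = _pick_state(conf_h, conf_e, conf_c)
            states.append(state)
            confs.append(conf)
    return "".join(states), confs


def _read_horiz(path: Path) -> tuple[str, list[float]]:
    pred_parts: list[str] = []
    conf_parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("Pred:"):
                pred_parts.append(line[5:].strip())
            elif line.startswith("Conf:"):
                conf_parts.append(line[5:].strip())
    states = "".join(pred_parts)
    conf_digits = "".join(conf_parts)
    if len(states) != len(conf_digits):
        raise ParseError(f"{path}: Pred/Conf length mismatch")
    states = states.replace("G", "H").replace("I", "H")  # fold rare DSSP-ish codes
    confs = [int(d) / 9.0 for d in conf_digits]
    return states, confs


def write_ss2(profile: SecondaryStructureProfile, path: str | Path,
              sequence: Optional[str] = None) -> None:
    """Write a profile in the ss2 per-residue layout (round-trippable)."""
    seq = sequence or "A" * len(profile)
    with open(path, "w") as fh:
        fh.write("# PSIPRED VFORMAT\n\n")
        for i, st in enumerate(profile.states):
            conf = profile.confidence[i] if profile.confidence else 1.0
            cc = conf if st == "C" else (1 - conf) / 2
            ch = conf if st == "H" else (1 - conf) / 2
            ce = conf if st == "E" else (1 - conf) / 2
            # perturb so the winning state is strictly maximal after rounding
            fh.write(f"{i + 1:>4} {seq[i]} {st}  {cc:6.3f} {ch:6.3f} {ce:6.3f}\n")


# ---------------------------------------------------------------------------
# Sidecar annotation tables (TMH spans, PPII scores, signal calls)
# ---------------------------------------------------------------------------

def read_tmh_table(path: str | Path) -> dict[str, tuple[int, int]]:
    """TSV of gene_id / tmh_start / tmh_end -> span mapping (1-based incl.)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    out: dict[str, tuple[int, int]] = {}
    for row in df.itertuples(index=False):
        s, e = int(row.tmh_start), int(row.tmh_end)
        if s > e or s < 1:
            raise ParseError(f"{path}: bad TMH span for {row.gene_id}")
        out[str(row.gene_id)] = (s, e)
    return out


def read_signal_table(path: str | Path) -> dict[str, str]:
    """TSV of gene_id / signal_call (none | sec_signal | lipoprotein)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    allowed = {"none", "sec_signal", "lipoprotein"}
    out = {}
    for row in df.itertuples(index=False):
        call = str(row.signal_call)
        # common external spellings
        call = {"SP(lipo)": "lipoprotein", "LIPO": "lipoprotein",
                "SP": "sec_signal", "OTHER": "none"}.get(call, call)
        if call not in allowed:
            raise ParseError(f"{path}: unknown signal call {row.signal_call!r}")
        out[str(row.gene_id)] = call
    return out


def read_ppii_scores(path: str | Path) -> dict[str, list[float]]:
    """TSV of gene_id / comma-separated per-residue PPII propensities."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = {}
    for row in df.itertuples(index=False):
        scores = [float(x) for x in str(row.ppii_scores).split(",")]
        if any(not (0.0 <= s <= 1.0) for s in scores):
            raise ParseError(f"{path}: PPII score outside [0,1] for {row.gene_id}")
        out[str(row.gene_id)] = scores
    return out


# ---------------------------------------------------------------------------
# Result tables and run manifest
# ---------------------------------------------------------------------------

def _df_to_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_tables(results: dict[str, pd.DataFrame], out_dir: str | Path,
                 config: Optional[dict] = None, seed: Optional[int] = None) -> dict[str, Path]:
    """Write result DataFrames as TSVs plus a JSON run manifest.

    ``results`` maps a table name (e.g. ``loci``, ``system_calls``,
    ``architectures``, ``cohort_summary``) to its DataFrame.  Output is
    deterministic: same inputs and config give byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in results.items():
        p = out_dir / f"{name}.tsv"
        _df_to_tsv(df, p)
        written[name] = p
    config = config or {}
    manifest = {
        "config": config,
        "config_hash": config_hash(config),
        "seed": seed,
        "tables": {n: p.name for n, p in written.items()},
    }
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    written["manifest"] = mpath
    return written


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by write_tables."""
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=["NA"])
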