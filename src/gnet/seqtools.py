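"""Promoter extraction and file exchange with external motif tools.

Extracts fixed-length upstream (promoter) windows for module genes from a
genome FASTA + GFF3 annotation, oriented 5'->3' relative to the gene
(reverse-complemented for minus-strand genes), and writes them as FASTA for
motif discovery with MEME.  Motif discovery itself and motif-motif
comparison (TomTom/JASPAR) run externally; a parser ingests their summary
table and flags putative sites at the p < 0.001 cutoff.

Coordinate conventions: GFF3 is 1-based inclusive; internally everything is
0-based half-open on the forward strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GnetError

logger = logging.getLogger(__name__)

MOTIF_P_CUTOFF = 1e-3
DEFAULT_WINDOW = 500


@dataclass
class UpstreamRegion:
    """A promoter window on the forward strand, promoter-oriented sequence."""

    gene_id: str
    contig: str
    start: int   # 0-based half-open, forward strand
    end: int
    strand: str  # '+' or '-'
    sequence: str

    def __post_init__(self):
        if self.end - self.start != len(self.sequence):
            raise GnetError("coordinate span does not match sequence length")
        if not set(self.sequence.upper()) <= set("ACGTN"):
            raise GnetError("sequence contains non-ACGTN characters")


def _tss_position(db: gffutils.FeatureDB, feature) -> int:
    """0-based forward-strand position of the translation start.

    Uses the 5'-most CDS boundary when CDS children exist; otherwise the
    gene feature's own 5' end.
    """
    cds = list(db.children(feature, featuretype="CDS"))
    if feature.strand == "+":
        pos1 = min(c.start for c in cds) if cds else feature.start
        return pos1 - 1          # first base of the feature, 0-based
    pos1 = max(c.end for c in cds) if cds else feature.end
    return pos1                  # one past the last base, 0-based half-open


def extract_upstream(genome_fasta, gff3_path, gene_ids,
                     window: int = DEFAULT_WINDOW) -> list[UpstreamRegion]:
    """Extract upstream windows for the requested genes.

    Plus-strand gene with 5' end at 0-based position s: window is
    [max(0, s - window), s).  Minus-strand gene with 5' end at half-open
    position e: window is [e, min(contig_len, e + window)), then
    reverse-complemented so the returned sequence reads toward the gene.
    Windows are truncated at contig edges.

    Genes missing from the GFF3 are skipped with a warning; a contig named
    in the GFF3 but absent from the FASTA is a hard error.
    """
    if window <= 0:
        raise GnetError("window must be positive")
    contigs = {rec.id: str(rec.seq).upper()
               for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    db = gffutils.create_db(str(gff3_path), dbfn=":memory:",
                            merge_strategy="create_unique", keep_order=True)
    regions = []
    for gid in gene_ids:
        try:
            feat = db[gid]
        except gffutils.FeatureNotFoundError:
            logger.warning("gene %s not found in GFF3; omitted", gid)
            continue
        if feat.seqid not in contigs:
            raise GnetError(f"contig {feat.seqid} missing from FASTA")
        seq = contigs[feat.seqid]
        if feat.strand == "+":
            tss = _tss_position(db, feat)
            start, end = max(0, tss - window), tss
            s = seq[start:end]
        else:
            tss = _tss_position(db, feat)
            start, end = tss, min(len(seq), tss + window)
            s = str(Seq(seq[start:end]).reverse_complement())
        if end <= start:
            logger.warning("gene %s has an empty upstream window; omitted", gid)
            continue
        regions.append(UpstreamRegion(gid, feat.seqid, start, end,
                                      feat.strand, s))
    return regions


def export_motif_fasta(regions: list[UpstreamRegion], path,
                       write_settings: bool = True) -> None:
    """Write promoter windows as FASTA for external motif discovery.

    A sidecar text file ``<path>.meme_settings.txt`` records the intended
    MEME parameters (motif width 6-18 nt; site p-value < 0.001) so the
    external run matches the analysis protocol.
    """
    if not regions:
        raise GnetError("no regions to export")
    records = [SeqRecord(Seq(r.sequence), id=r.gene_id, description="")
               for r in regions]
    SeqIO.write(records, str(path), "fasta")
    if write_settings:
        with open(f"{path}.meme_settings.txt", "w") as fh:
            fh.write("# Suggested MEME settings for promoter motif discovery\n"
                     "minw = 6\nmaxw = 18\n"
                     f"site p-value cutoff = {MOTIF_P_CUTOFF}\n")


def load_motif_hits(path) -> pd.DataFrame:
    """Parse an external motif-hit summary (TSV).

    Requires columns module_id, consensus, p_value; extra columns (matched
    TF motif, TF family, ...) pass through.  Rows with unparseable p-values
    are dropped with a warning.  Adds a boolean ``putative`` column marking
    sites with p < 0.001.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["module_id", "consensus", "p_value",
                                     "putative"])
    for col in ("module_id", "consensus", "p_value"):
        if col not in df.columns:
            raise GnetError(f"motif hit table missing column {col}")
    p = pd.to_numeric(df["p_value"], errors="coerce")
    bad = p.isna() | df["consensus"].isna() | df["module_id"].isna()
    if bad.any():
        logger.warning("skipping %d malformed motif row(s)", int(bad.sum()))
        df, p = df[~bad].copy(), p[~bad]
    df["p_value"] = p
    df["putative"] = p < MOTIF_P_CUTOFF
    return df.reset_index(drop=True)
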