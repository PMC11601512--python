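"""Padlock encoding-probe design for RCA-amplified multiplexed FISH.

Each target (an endogenous transcript or a 185-mer perturbation barcode) is
tiled with 60-nt windows that split into two 30-nt halves. The two probe
arms are the reverse complements of those halves: upon hybridization they
abut on the target and are ligated into a circle, which is then amplified
by rolling circle amplification (RCA) into a bright amplicon. Between the
arms the probe carries an RCA primer site and the reverse complements of
the readout sequences for the on-bits of the target's codeword; terminal
PCR handles carry BciVI (left) and BccI (right) Type IIS restriction sites
used to liberate full-length, 5'-phosphorylated probes after synthesis.

Candidate windows are filtered on per-arm GC content (30-70%), nearest-
neighbor melting temperature (60-80 degC), gene/isoform specificity indices
(unique-15-mer fractions, >= 0.75 / >= 0.7), absence of >15-nt homology to
rRNA/tRNA, and the ligation-junction rule: windows whose donor
(5'-phosphorylated) arm starts with G or C are excluded, since SplintR-type
ligases discriminate poorly at G/C donors.

Arm convention: the donor arm targets the left half of the window
(``[start, start+30)``) and the acceptor arm the right half; the donor's
5' base therefore pairs with the target base at ``start+29``. Coordinates
are recorded on every probe, so the opposite convention is reconstructable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqUtils import MeltingTemp as _mt

from .codebook import Codebook, Codeword

__all__ = [
    "CandidateSite",
    "EncodingProbe",
    "ProbeFilters",
    "KmerIndex",
    "ContaminantIndex",
    "ReadoutPool",
    "melting_temperature",
    "specificity_indices",
    "evaluate_candidate",
    "design_probe_set",
    "assemble_padlock",
    "reverse_complement",
    "make_readout_pool",
    "InternalRestrictionSiteError",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Type IIS recognition sites used to liberate probes from the synthesis
#: concatemer. BciVI cuts downstream of GTATCC; BccI downstream of CCATC.
BCIVI_SITE = "GTATCC"
BCCI_SITE = "CCATC"

#: RCA primer printed in the protocol (phosphorothioate marks dropped).
RCA_PRIMER_FULL = "TCTTCACCCGGGGCAGCTGAAGT"
#: Default 20-nt primer-binding site placed on the probe backbone; see the
#: methods note for why the default site is 20 nt.
DEFAULT_RCA_PRIMER_SITE = RCA_PRIMER_FULL[:20]

DEFAULT_HANDLE_LEFT = "CGTTA" + BCIVI_SITE + "AGGA"  # 15 nt, BciVI inside
DEFAULT_HANDLE_RIGHT = "AGTG" + BCCI_SITE + "TAGGTA"  # 15 nt, BccI inside

ARM_LENGTH = 30
WINDOW_LENGTH = 2 * ARM_LENGTH


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class InternalRestrictionSiteError(ValueError):
    def __init__(self, site: str, position: int):
        super().__init__(
            f"probe body contains internal {site} recognition site at position {position}"
        )
        self.site = site
        self.position = position


# --------------------------------------------------------------------------
# thermodynamics


def melting_temperature(
    sequence: str,
    na_molar: float = 0.3,
    formamide_percent: float = 0.0,
    formamide_coef: float = 0.6,
) -> float:
    """Nearest-neighbor duplex melting temperature in degC.

    SantaLucia unified nearest-neighbor parameters with the entropy salt
    correction at ``na_molar`` monovalent salt, and a linear formamide
    correction of ``formamide_coef`` degC per percent formamide.
    """
    seq = sequence.upper()
    if len(seq) < 8:
        raise ValueError("sequence must be at least 8 nt")
    if set(seq) - set("ACGT"):
        raise ValueError(f"ambiguous bases in sequence: {set(seq) - set('ACGT')}")
    tm = _mt.Tm_NN(
        seq,
        nn_table=_mt.DNA_NN3,
        Na=na_molar * 1000.0,
        saltcorr=5,
        dnac1=25.0,
        dnac2=25.0,
    )
    return float(tm) - formamide_coef * formamide_percent


def gc_fraction(seq: str) -> float:
    seq = seq.upper()
    return (seq.count("G") + seq.count("C")) / len(seq)


# --------------------------------------------------------------------------
# specificity


class KmerIndex:
    """k-mer -> {genes}, {isoforms} lookup over a transcriptome.

    ``transcripts`` maps isoform id -> sequence; ``isoform_to_gene`` maps
    isoform id -> gene id (defaults to identity, i.e. one isoform per gene).
    """

    def __init__(self, transcripts: dict, isoform_to_gene: dict | None = None, k: int = 15):
        self.k = int(k)
        self.isoform_to_gene = dict(isoform_to_gene or {t: t for t in transcripts})
        self._genes: dict = {}
        self._isoforms: dict = {}
        for iso, seq in transcripts.items():
            gene = self.isoform_to_gene.get(iso, iso)
            s = str(seq).upper()
            for i in range(len(s) - self.k + 1):
                kmer = s[i : i + self.k]
                self._genes.setdefault(kmer, set()).add(gene)
                self._isoforms.setdefault(kmer, set()).add(iso)

    @classmethod
    def from_fasta(cls, path, k: int = 15, isoform_to_gene: dict | None = None) -> "KmerIndex":
        from Bio import SeqIO

        transcripts = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(transcripts, isoform_to_gene, k=k)

    def genes_of(self, kmer: str) -> set:
        return self._genes.get(kmer, set())

    def isoforms_of(self, kmer: str) -> set:
        return self._isoforms.get(kmer, set())


def specificity_indices(
    sequence: str,
    index: KmerIndex,
    gene: str,
    isoform: str | None = None,
) -> tuple:
    """(gene_si, isoform_si) as unique-k-mer fractions.

    gene_si: fraction of the sequence's k-mers found in no gene other than
    ``gene``. isoform_si: fraction found in no other isoform of the same
    gene (k-mers hitting other genes do not count against isoform_si; they
    are penalized by gene_si).
    """
    seq = sequence.upper()
    k = index.k
    if k > len(seq):
        raise ValueError(f"k={k} exceeds sequence length {len(seq)}")
    iso = isoform if isoform is not None else gene
    siblings = {
        i for i, g in index.isoform_to_gene.items() if g == gene and i != iso
    }
    n = len(seq) - k + 1
    gene_ok = 0
    iso_ok = 0
    for i in range(n):
        kmer = seq[i : i + k]
        if index.genes_of(kmer) <= {gene}:
            gene_ok += 1
        if not (index.isoforms_of(kmer) & siblings):
            iso_ok += 1
    return gene_ok / n, iso_ok / n


class ContaminantIndex:
    """Longest exact-match lookup against rRNA/tRNA sequences (both strands)."""

    def __init__(self, sequences: dict | list | None):
        seqs = []
        if sequences:
            vals = sequences.values() if isinstance(sequences, dict) else sequences
            for s in vals:
                s = str(s).upper()
                seqs.append(s)
                seqs.append(reverse_complement(s))
        self._text = "#".join(seqs)

    @classmethod
    def from_fasta(cls, path) -> "ContaminantIndex":
        from Bio import SeqIO

        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def longest_match(self, seq: str) -> int:
        """Length of the longest exact substring shared with any contaminant."""
        if not self._text:
            return 0
        seq = seq.upper()

        def has_match(length: int) -> bool:
            for i in range(len(seq) - length + 1):
                if seq[i : i + length] in self._text:
                    return True
            return False

        lo, hi, best = 1, len(seq), 0
        while lo <= hi:
            mid = (lo + hi) // 2
            if has_match(mid):
                best = mid
                lo = mid + 1
            else:
                hi = mid - 1
        return best


# --------------------------------------------------------------------------
# candidate sites and filters


@dataclass
class CandidateSite:
    transcript_id: str
    start: int  # 0-based; window is [start, start + 60)
    arm_donor: str  # 5'-phosphorylated arm, targets [start, start+30)
    arm_acceptor: str  # 3' arm, targets [start+30, start+60)
    gc_donor: float
    gc_acceptor: float
    tm_donor: float
    tm_acceptor: float
    gene_si: float
    isoform_si: float
    junction_base: str  # 5' base of the donor arm
    max_rrna_match: int


@dataclass
class ProbeFilters:
    """Printed candidate-filter thresholds."""

    gc_range: tuple = (0.30, 0.70)
    tm_range: tuple = (60.0, 80.0)
    gene_si_range: tuple = (0.75, 1.0)
    isoform_si_range: tuple = (0.70, 1.0)
    max_contaminant_match: int = 15
    forbidden_junction_bases: tuple = ("G", "C")


@dataclass(frozen=True)
class Verdict:
    passed: bool
    rules: dict


def make_candidate(
    transcript_id: str,
    sequence: str,
    start: int,
    index: KmerIndex,
    contaminants: ContaminantIndex,
    gene: str | None = None,
    isoform: str | None = None,
    na_molar: float = 0.3,
    formamide_percent: float = 0.0,
) -> CandidateSite:
    window = sequence[start : start + WINDOW_LENGTH].upper()
    left, right = window[:ARM_LENGTH], window[ARM_LENGTH:]
    donor = reverse_complement(left)
    acceptor = reverse_complement(right)
    gene = gene if gene is not None else transcript_id
    gsi, isi = specificity_indices(window, index, gene, isoform or transcript_id)
    return CandidateSite(
        transcript_id=transcript_id,
        start=start,
        arm_donor=donor,
        arm_acceptor=acceptor,
        gc_donor=gc_fraction(donor),
        gc_acceptor=gc_fraction(acceptor),
        tm_donor=melting_temperature(donor, na_molar, formamide_percent),
        tm_acceptor=melting_temperature(acceptor, na_molar, formamide_percent),
        gene_si=gsi,
        isoform_si=isi,
        junction_base=donor[0],
        max_rrna_match=max(
            contaminants.longest_match(donor), contaminants.longest_match(acceptor)
        ),
    )


def evaluate_candidate(site: CandidateSite, filters: ProbeFilters | None = None) -> Verdict:
    """Per-rule verdicts; the site passes iff every rule passes."""
    f = filters or ProbeFilters()
    lo_gc, hi_gc = f.gc_range
    lo_tm, hi_tm = f.tm_range
    rules = {
        "gc_donor": lo_gc <= site.gc_donor <= hi_gc,
        "gc_acceptor": lo_gc <= site.gc_acceptor <= hi_gc,
        "tm_donor": lo_tm <= site.tm_donor <= hi_tm,
        "tm_acceptor": lo_tm <= site.tm_acceptor <= hi_tm,
        "gene_si": f.gene_si_range[0] <= site.gene_si <= f.gene_si_range[1],
        "isoform_si": f.isoform_si_range[0] <= site.isoform_si <= f.isoform_si_range[1],
        "contaminant": site.max_rrna_match <= f.max_contaminant_match,
        "junction": site.junction_base not in f.forbidden_junction_bases,
    }
    return Verdict(passed=all(rules.values()), rules=rules)


# --------------------------------------------------------------------------
# readout pool


@dataclass
class ReadoutPool:
    """One readout sequence per codebook bit (the dye-labeled oligo sequence)."""

    sequences: list  # index = bit

    def __len__(self):
        return len(self.sequences)

    def complement_of_bit(self, bit: int) -> str:
        return reverse_complement(self.sequences[bit])

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"bit": range(len(self.sequences)), "sequence": self.sequences}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ReadoutPool":
        df = pd.read_csv(path, sep="\t").sort_values("bit")
        return cls(sequences=list(df["sequence"]))


def make_readout_pool(n_bits: int, length: int = 15, seed: int = 0) -> ReadoutPool:
    """Seeded random readout sequences, free of the liberation-enzyme sites,
    with moderate GC and no homopolymer longer than 3."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    forbidden = [BCIVI_SITE, BCCI_SITE,
                 reverse_complement(BCIVI_SITE), reverse_complement(BCCI_SITE)]
    seqs: list = []
    while len(seqs) < n_bits:
        seq = "".join(rng.choice(bases, size=length))
        gc = gc_fraction(seq)
        if not (0.33 <= gc <= 0.67):
            continue
        if any(b * 4 in seq for b in "ACGT"):
            continue
        if any(m in seq for m in forbidden):
            continue
        if seq in seqs:
            continue
        seqs.append(seq)
    return ReadoutPool(sequences=seqs)


# --------------------------------------------------------------------------
# assembly


@dataclass
class EncodingProbe:
    target: str
    site: CandidateSite
    readout_complements: list
    rca_primer_site: str
    handle_left: str
    handle_right: str
    full_sequence: str
    codeword_index: int
    on_bits: tuple

    @property
    def body(self) -> str:
        """Liberated probe: arms + backbone, without the PCR handles."""
        return self.full_sequence[len(self.handle_left) : len(self.full_sequence) - len(self.handle_right)]

    @property
    def length(self) -> int:
        return len(self.body)


def _find_internal_site(body: str) -> tuple | None:
    for motif in (BCIVI_SITE, BCCI_SITE):
        for probe_motif in (motif, reverse_complement(motif)):
            pos = body.find(probe_motif)
            if pos != -1:
                return motif, pos
    return None


def assemble_padlock(
    site: CandidateSite,
    codeword: Codeword,
    readout_pool: ReadoutPool,
    target: str | None = None,
    rca_primer_site: str = DEFAULT_RCA_PRIMER_SITE,
    handle_left: str = DEFAULT_HANDLE_LEFT,
    handle_right: str = DEFAULT_HANDLE_RIGHT,
) -> EncodingProbe:
    """Assemble the full padlock sequence for one candidate site.

    Layout 5'->3': handle_left | donor arm | RCA primer site | readout
    complements (one per on-bit) | acceptor arm | handle_right. After Type
    IIS digestion the liberated probe runs donor arm -> backbone -> acceptor
    arm, with the donor 5' end phosphorylated; circularization on the target
    abuts the acceptor 3' end against the donor 5' end.
    """
    if len(readout_pool) < len(codeword.bits):
        raise ValueError("readout pool must define a sequence for every bit")
    complements = [readout_pool.complement_of_bit(b) for b in codeword.on_bits]
    backbone = rca_primer_site + "".join(complements)
    body = site.arm_donor + backbone + site.arm_acceptor
    hit = _find_internal_site(body)
    if hit is not None:
        raise InternalRestrictionSiteError(hit[0], hit[1])
    full = handle_left + body + handle_right
    return EncodingProbe(
        target=target if target is not None else site.transcript_id,
        site=site,
        readout_complements=complements,
        rca_primer_site=rca_primer_site,
        handle_left=handle_left,
        handle_right=handle_right,
        full_sequence=full,
        codeword_index=codeword.index,
        on_bits=codeword.on_bits,
    )


# --------------------------------------------------------------------------
# probe-set design


def _maximal_nonoverlapping(starts: list) -> list:
    """Earliest-end greedy: a maximum-size set of non-overlapping windows."""
    chosen: list = []
    last_end = -1
    for s in sorted(starts):
        if s >= last_end:
            chosen.append(s)
            last_end = s + WINDOW_LENGTH
    return chosen


def _spread_selection(starts: list, n_probes: int) -> list:
    """Pick n_probes non-overlapping starts spread evenly along the target."""
    starts = sorted(starts)
    anchors = np.linspace(starts[0], starts[-1], n_probes)
    chosen: list = []
    last_end = -1
    remaining = list(starts)
    for a in anchors:
        feasible = [s for s in remaining if s >= last_end]
        if not feasible:
            break
        s = min(feasible, key=lambda s: abs(s - a))
        chosen.append(s)
        last_end = s + WINDOW_LENGTH
        remaining = [r for r in remaining if r >= last_end]
    return chosen


def design_probe_set(
    transcript_id: str,
    sequence: str,
    codeword: Codeword,
    readout_pool: ReadoutPool,
    n_probes: int,
    index: KmerIndex,
    contaminants: ContaminantIndex | None = None,
    filters: ProbeFilters | None = None,
    step: int = 5,
    gene: str | None = None,
    isoform: str | None = None,
    **assemble_kwargs,
) -> list:
    """Design up to ``n_probes`` non-overlapping encoding probes for a target.

    Tiles 60-nt candidate windows at ``step`` nt, filters them through
    :func:`evaluate_candidate`, then selects non-overlapping sites that
    maximize spread along the transcript. Emits a warning (never an error)
    when fewer than ``n_probes`` passing sites survive.
    """
    sequence = str(sequence).upper()
    if len(sequence) < WINDOW_LENGTH:
        raise ValueError("transcript shorter than one 60-nt window")
    contaminants = contaminants or ContaminantIndex(None)
    filters = filters or ProbeFilters()

    # backbone is fixed per codeword; pre-build it so candidates whose arms
    # would introduce an internal liberation-enzyme site are rejected here
    backbone = assemble_kwargs.get("rca_primer_site", DEFAULT_RCA_PRIMER_SITE) + "".join(
        readout_pool.complement_of_bit(b) for b in codeword.on_bits
    )

    passing: dict = {}
    for start in range(0, len(sequence) - WINDOW_LENGTH + 1, step):
        site = make_candidate(
            transcript_id, sequence, start, index, contaminants,
            gene=gene, isoform=isoform,
        )
        if not evaluate_candidate(site, filters).passed:
            continue
        if _find_internal_site(site.arm_donor + backbone + site.arm_acceptor):
            continue
        passing[start] = site

    if not passing:
        warnings.warn(
            f"{transcript_id}: no candidate site passed the filters; empty probe set"
        )
        return []

    maximal = _maximal_nonoverlapping(list(passing))
    if len(maximal) <= n_probes:
        chosen = maximal
    else:
        chosen = _spread_selection(list(passing), n_probes)

    if len(chosen) < n_probes:
        warnings.warn(
            f"{transcript_id}: only {len(chosen)} of {n_probes} requested "
            "probes could be placed"
        )

    return [
        assemble_padlock(passing[s], codeword, readout_pool,
                         target=transcript_id, **assemble_kwargs)
        for s in sorted(chosen)
    ]


# --------------------------------------------------------------------------
# synthetic design targets


def random_transcript(length: int = 2000, seed: int = 0, gc: float = 0.5) -> str:
    """Random transcript with the stated GC content.

    At ``gc=0.5`` and desk-scale lengths the 15-mers are globally unique
    with overwhelming probability, making the transcript permissive for
    probe design (abundant passing candidate sites).
    """
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(np.array(list("ACGT")), size=length, p=p))


def design_random_barcode(
    codeword: Codeword,
    readout_pool: ReadoutPool,
    n_probes: int = 3,
    length: int = 185,
    seed: int = 0,
    max_tries: int = 200,
    **design_kwargs,
) -> tuple:
    """Draw a random barcode sequence that admits ``n_probes`` probes.

    Mirrors how imaging barcodes are designed rather than found: candidate
    barcode sequences are drawn until one supports the requested number of
    non-overlapping passing padlock sites (a 185-mer fits three 60-nt
    windows only under near-exact tiling, so not every random sequence
    qualifies). Returns ``(sequence, probes)``.
    """
    for t in range(max_tries):
        seq = random_transcript(length, seed=seed * max_tries + t)
        index = KmerIndex({"barcode": seq})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            probes = design_probe_set(
                "barcode", seq, codeword, readout_pool, n_probes, index,
                **design_kwargs,
            )
        if len(probes) == n_probes:
            return seq, probes
    raise RuntimeError(
        f"no {length}-mer admitting {n_probes} probes found in {max_tries} draws"
    )


def probes_to_frame(probes: list) -> pd.DataFrame:
    rows = []
    for p in probes:
        rows.append(
            {
                "target": p.target,
                "transcript": p.site.transcript_id,
                "start": p.site.start,
                "arm_donor": p.site.arm_donor,
                "arm_acceptor": p.site.arm_acceptor,
                "gc_donor": p.site.gc_donor,
                "gc_acceptor": p.site.gc_acceptor,
                "tm_donor": p.site.tm_donor,
                "tm_acceptor": p.site.tm_acceptor,
                "gene_si": p.site.gene_si,
                "isoform_si": p.site.isoform_si,
                "junction_base": p.site.junction_base,
                "max_rrna_match": p.site.max_rrna_match,
                "on_bits": ";".join(map(str, p.on_bits)),
                "length": p.length,
                "full_sequence": p.full_sequence,
            }
        )
    return pd.DataFrame(rows)


def probes_to_fasta(probes: list, path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(probes):
            fh.write(f">{p.target}_probe{i}_start{p.site.start}\n{p.full_sequence}\n")
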