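"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study conditions the analyses assume: a
genome with restriction sites planted at known (Poisson-spaced)
positions, read pairs drawn from a contact model combining power-law
distance decay, block compartment structure and per-fragment
multiplicative bias, and annotation/read/methylation files whose
resulting tracks differ between the planted compartments by a stated
effect size.  Every generator is seed-deterministic: the same seed
yields byte-identical files.

Alignment files are minimal single-end SAM with only the fields the
readers use (name, flag, chromosome, position, MAPQ, CIGAR); read
sequences are placeholders since alignment happens upstream of this
package.  MAPQ is 60 for unique ends and 0 for planted non-unique ones.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pysam

from .genome_model import (
    FragmentSet,
    GenomeIndex,
    HicdeskError,
    RestrictionEnzyme,
    digest_genome,
)
from .preprocess import AlignedEnd, InteractionMatrix, ReadPair
from .tracks import MethylationCall, Track

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class ContactModel:
    """Planted ground-truth contact model.

    Intra-chromosomal pair weight:
    ``b_i * b_j * rho^[same block] * d_ij^-alpha`` with d the midpoint
    distance; inter-chromosomal weight ``b_i * b_j * inter_level``.
    """

    alpha: float = 0.85
    rho: float = 1.0
    block_labels: Optional[np.ndarray] = None  # per fragment, e.g. 'A'/'B'
    bias: Optional[np.ndarray] = None  # per fragment, > 0
    inter_level: float = 1e-9  # weight per inter-chromosomal pair, pre-bias
    min_distance: float = 1.0  # floor for d in the decay term (bp)

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise HicdeskError("decay exponent alpha must be >= 0")
        if self.rho < 1:
            raise HicdeskError("compartment contrast rho must be >= 1")
        if self.bias is not None and np.any(np.asarray(self.bias) <= 0):
            raise HicdeskError("bias vector must be positive")


def alternating_blocks(fragments: FragmentSet, block_size: int) -> np.ndarray:
    """'A'/'B' labels alternating every ``block_size`` fragments per chromosome."""
    labels = np.empty(len(fragments), dtype="<U1")
    for name in fragments.genome.names:
        lo, hi = fragments.chrom_slice(name)
        idx = np.arange(hi - lo) // block_size
        labels[lo:hi] = np.where(idx % 2 == 0, "A", "B")
    return labels


def _write_fasta(path: str, records: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def generate_genome(
    chrom_lengths: dict[str, int],
    enzyme: RestrictionEnzyme,
    mean_spacing: Optional[float],
    seed: int,
    fasta_path: Optional[str] = None,
) -> tuple[dict[str, str], dict[str, list[int]]]:
    """Random genome with enzyme sites planted at known positions.

    Sites are spaced by an exponential (Poisson process) with the given
    mean gap in bp; ``mean_spacing=None`` plants no sites.  Accidental
    motif occurrences elsewhere are mutated away, so the digest truth is
    exactly the planted positions.  Returns ({chrom: sequence},
    {chrom: sorted site start positions}).
    """
    site = enzyme.site
    rng = np.random.default_rng(seed)
    records: dict[str, str] = {}
    truth: dict[str, list[int]] = {}
    for name, length in chrom_lengths.items():
        if length < 1000:
            raise HicdeskError(f"chromosome {name} shorter than 1 kb")
        if mean_spacing is not None and mean_spacing < len(site) + 1:
            raise HicdeskError("mean site spacing incompatible with motif length")
        seq = rng.choice(_BASES, size=length)
        planted: list[int] = []
        if mean_spacing is not None:
            pos = int(rng.exponential(mean_spacing)) + 1
            while pos + len(site) <= length - 1:
                planted.append(pos)
                pos += len(site) + 1 + int(rng.exponential(mean_spacing))
        site_arr = np.frombuffer(site.encode(), dtype="S1")
        for p in planted:
            seq[p:p + len(site)] = site_arr
        in_site = np.zeros(length, dtype=bool)
        for p in planted:
            in_site[p:p + len(site)] = True
        # mutate away accidental occurrences without touching planted sites
        for _ in range(200):
            text = seq.tobytes().decode()
            extra = [
                i for i in _occurrences(text, site) if i not in set(planted)
            ]
            if not extra:
                break
            for occ in extra:
                free = [k for k in range(occ, occ + len(site)) if not in_site[k]]
                if not free:
                    continue
                k = free[len(free) // 2]
                current = seq[k]
                choices = [b for b in _BASES if b != current]
                seq[k] = choices[int(rng.integers(len(choices)))]
        else:
            raise HicdeskError(f"could not scrub accidental sites on {name}")
        records[name] = seq.tobytes().decode()
        truth[name] = planted
    if fasta_path:
        _write_fasta(fasta_path, records)
    return records, truth


def _occurrences(text: str, motif: str) -> list[int]:
    out, i = [], text.find(motif)
    while i != -1:
        out.append(i)
        i = text.find(motif, i + 1)
    return out


def truth_fragments(
    chrom_lengths: dict[str, int],
    truth_sites: dict[str, list[int]],
    enzyme: RestrictionEnzyme,
) -> dict[str, list[tuple[int, int]]]:
    """Expected fragment intervals per chromosome from the planted sites."""
    out = {}
    for name, length in chrom_lengths.items():
        cuts = sorted({p + enzyme.cut_offset for p in truth_sites[name]
                       if 0 < p + enzyme.cut_offset < length})
        bounds = [0] + cuts + [length]
        out[name] = list(zip(bounds[:-1], bounds[1:]))
    return out


@dataclass
class SimulatedPairs:
    pairs: list  # ReadPair, contacts plus injected artefacts
    truth: InteractionMatrix  # realized contact counts, artefacts excluded
    artefact_names: dict[str, str]  # read name -> 'inward' | 'outward'
    forward_sam: Optional[str] = None
    reverse_sam: Optional[str] = None


def _pair_weights(model: ContactModel, fragments: FragmentSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(fragments)
    mids = fragments.midpoints
    codes = fragments.chrom_codes
    bias = np.ones(n) if model.bias is None else np.asarray(model.bias, float)
    iu, ju = np.triu_indices(n, k=1)
    w = bias[iu] * bias[ju]
    intra = codes[iu] == codes[ju]
    d = np.maximum(np.abs(mids[ju] - mids[iu]), model.min_distance)
    w_intra = d ** (-model.alpha)
    if model.block_labels is not None:
        same = np.asarray(model.block_labels)[iu] == np.asarray(model.block_labels)[ju]
        w_intra = w_intra * np.where(same, model.rho, 1.0)
    w = w * np.where(intra, w_intra, model.inter_level)
    return iu, ju, w


def simulate_pairs(
    model: ContactModel,
    fragments: FragmentSet,
    n_pairs: int,
    seed: int,
    artefact_fraction: float = 0.0,
    inward_span: tuple[int, int] = (50, 500),
    outward_span: tuple[int, int] = (50, 5000),
    expand_pairs: bool = True,
    sam_prefix: Optional[str] = None,
    read_length: int = 50,
    protect_from_filter: Optional[tuple[int, int]] = None,
) -> SimulatedPairs:
    """Draw read pairs from the contact model; optionally inject artefacts.

    ``n_pairs`` genuine contacts are drawn multinomially over fragment
    pairs; end positions are uniform within each fragment and strands
    random.  ``artefact_fraction`` adds that fraction (of n_pairs) of
    short inward plus as many outward pairs with spans drawn from the
    given ranges; artefact read names are recorded so filtering can be
    verified exactly.  With ``protect_from_filter=(inward, outward)``,
    genuine intra-chromosomal contacts whose span falls below the
    respective threshold are given same-strand orientation, so the
    proximity filter at those thresholds removes injected artefacts and
    nothing else.  The returned truth matrix holds the realized genuine
    contact counts.  With ``sam_prefix`` two single-end SAM files
    (<prefix>_fwd.sam / <prefix>_rev.sam) are written.
    """
    if n_pairs < 1:
        raise HicdeskError("n_pairs must be >= 1")
    if len(fragments) == 0:
        raise HicdeskError("empty fragment set")
    rng = np.random.default_rng(seed)
    iu, ju, w = _pair_weights(model, fragments)
    p = w / w.sum()
    counts = rng.multinomial(n_pairs, p)
    truth = InteractionMatrix.from_triplets(
        fragments, iu[counts > 0], ju[counts > 0], counts[counts > 0].astype(float)
    )

    pairs: list[ReadPair] = []
    artefacts: dict[str, str] = {}
    chrom_order = {n: i for i, n in enumerate(fragments.genome.names)}
    if expand_pairs or sam_prefix:
        sel = np.flatnonzero(counts)
        rid = 0
        for k in sel:
            i, j = int(iu[k]), int(ju[k])
            ci = fragments.genome.names[fragments.chrom_codes[i]]
            cj = fragments.genome.names[fragments.chrom_codes[j]]
            for _ in range(int(counts[k])):
                pi = int(rng.integers(fragments.starts[i], fragments.ends[i]))
                pj = int(rng.integers(fragments.starts[j], fragments.ends[j]))
                si = "+-"[int(rng.integers(2))]
                sj = "+-"[int(rng.integers(2))]
                if protect_from_filter is not None and ci == cj:
                    span = abs(pj - pi)
                    if (si != sj and span < max(protect_from_filter)):
                        up_plus = (si == "+") == (pi <= pj)
                        limit = protect_from_filter[0 if up_plus else 1]
                        if span < limit:
                            sj = si
                name = f"contact_{rid}"
                rid += 1
                pairs.append(ReadPair.make(
                    AlignedEnd(name, ci, pi, si), AlignedEnd(name, cj, pj, sj),
                    chrom_order))
        n_art = int(round(artefact_fraction * n_pairs))
        for kind, (lo_s, hi_s), strands in (
            ("inward", inward_span, ("+", "-")),
            ("outward", outward_span, ("-", "+")),
        ):
            for a in range(n_art):
                ci = fragments.genome.names[int(rng.integers(len(fragments.genome)))]
                L = fragments.genome.lengths[ci]
                span = int(rng.integers(lo_s, hi_s))
                span = min(span, L - 2)
                pos = int(rng.integers(0, L - span))
                name = f"art{kind[:3]}_{a}"
                artefacts[name] = kind
                pairs.append(ReadPair.make(
                    AlignedEnd(name, ci, pos, strands[0]),
                    AlignedEnd(name, ci, pos + span, strands[1]),
                    chrom_order))

    fwd = rev = None
    if sam_prefix:
        fwd = f"{sam_prefix}_fwd.sam"
        rev = f"{sam_prefix}_rev.sam"
        _write_pair_sams(pairs, fragments.genome, fwd, rev, read_length)
    return SimulatedPairs(pairs, truth, artefacts, fwd, rev)


def _write_pair_sams(
    pairs: Sequence[ReadPair],
    genome: GenomeIndex,
    fwd_path: str,
    rev_path: str,
    read_length: int,
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": genome.lengths[n]} for n in genome.names],
    }
    ref_id = {n: i for i, n in enumerate(genome.names)}
    with pysam.AlignmentFile(fwd_path, "w", header=header) as f1, \
            pysam.AlignmentFile(rev_path, "w", header=header) as f2:
        for p in pairs:
            for end, fh in ((p.end1, f1), (p.end2, f2)):
                a = pysam.AlignedSegment()
                a.query_name = end.name
                a.reference_id = ref_id[end.chrom]
                a.mapping_quality = 60 if end.unique else 0
                L = genome.lengths[end.chrom]
                if end.strand == "+":
                    rl = min(read_length, L - end.position)
                    a.reference_start = end.position
                else:
                    a.flag = 16
                    rl = min(read_length, end.position + 1)
                    a.reference_start = end.position - rl + 1
                a.cigarstring = f"{rl}M"
                fh.write(a)


def simulate_tracks(
    fragments: FragmentSet,
    labels: np.ndarray,
    effect_size: float,
    seed: int,
    outdir: Optional[str] = None,
    base_count: float = 5.0,
    base_density: float = 30.0,
    base_methylation: float = 0.3,
    total_per_site: int = 20,
    site_spacing: int = 100,
    read_length: int = 30,
) -> dict:
    """Tracks (and optionally files) that differ between planted compartments.

    Fragments labelled 'A' carry ``effect_size`` times the base level of
    each signal ('B' fragments the base level): gene features (GFF, each
    strictly inside its fragment, so each contributes 0.5), short reads
    (SAM counts), coverage elements (SAM density), and methylation calls
    (TSV, binomial per site).  ``effect_size=1`` is the null.  Returns
    truth tracks and, when ``outdir`` is given, the file paths.
    """
    if effect_size <= 0:
        raise HicdeskError("effect size must be positive")
    rng = np.random.default_rng(seed)
    n = len(fragments)
    labels = np.asarray(labels)
    boost = np.where(labels == "A", effect_size, 1.0)

    gene_n = rng.poisson(base_count * boost)
    read_n = rng.poisson(base_count * boost)
    dens_frac = np.clip(base_density * boost, 0, 95) / 100.0
    meth_p = np.clip(base_methylation * boost, 0.0, 0.98)

    genes = []  # (chrom, start0, end0) strictly inside the fragment
    reads = []  # (chrom, pos, strand)
    elements = []  # (chrom, start0, end0) one per fragment covering dens_frac
    calls = []
    meth_track = np.full(n, np.nan)
    for i in range(n):
        f = fragments[i]
        for _ in range(int(gene_n[i])):
            if f.length < 4:
                gene_n[i] -= 1
                continue
            s = int(rng.integers(f.start + 1, f.end - 2))
            e = int(rng.integers(s + 1, f.end - 1)) + 1
            genes.append((f.chrom, s, min(e, f.end - 1)))
        for _ in range(int(read_n[i])):
            reads.append((f.chrom, int(rng.integers(f.start, f.end)), "+"))
        cov = int(round(dens_frac[i] * f.length))
        if cov > 0:
            s = int(rng.integers(f.start, f.end - cov + 1))
            elements.append((f.chrom, s, s + cov))
        m_tot = m_met = 0
        for pos in range(f.start + site_spacing // 2, f.end, site_spacing):
            met = int(rng.binomial(total_per_site, meth_p[i]))
            calls.append(MethylationCall(f.chrom, pos, met, total_per_site))
            m_tot += total_per_site
            m_met += met
        if m_tot:
            meth_track[i] = 100.0 * m_met / m_tot

    dens_track = np.zeros(n)
    for chrom, s, e in elements:
        i = fragments.locate(chrom, s)
        dens_track[i] = 100.0 * (e - s) / fragments.lengths[i]

    truth = {
        "gene": Track("gene", "annotation_count", 0.5 * gene_n),
        "reads": Track("reads", "short_count", read_n.astype(float)),
        "coverage": Track("coverage", "density", dens_track),
        "methylation": Track("methylation", "methylation_density", meth_track),
    }
    out = {"tracks": truth, "genes": genes, "reads": reads,
           "elements": elements, "calls": calls}

    if outdir:
        os.makedirs(outdir, exist_ok=True)
        gff = os.path.join(outdir, "annotation.gff3")
        with open(gff, "w") as fh:
            fh.write("##gff-version 3\n")
            for k, (chrom, s, e) in enumerate(genes):
                fh.write(f"{chrom}\tsim\tgene\t{s + 1}\t{e}\t.\t+\t.\tID=g{k}\n")
        reads_sam = os.path.join(outdir, "short_reads.sam")
        _write_feature_sam(reads_sam, fragments.genome,
                           [(c, p, p + 1) for c, p, _s in reads])
        dens_sam = os.path.join(outdir, "coverage.sam")
        _write_feature_sam(dens_sam, fragments.genome, elements)
        meth_tsv = os.path.join(outdir, "methylation.tsv")
        with open(meth_tsv, "w") as fh:
            fh.write("chrom\tpos\tmethylated\ttotal\n")
            for c in calls:
                fh.write(f"{c.chrom}\t{c.position + 1}\t{c.methylated}\t{c.total}\n")
        out["files"] = {"gff": gff, "short_sam": reads_sam,
                        "density_sam": dens_sam, "methylation_tsv": meth_tsv}
    return out


def _write_feature_sam(path: str, genome: GenomeIndex,
                       intervals: Sequence[tuple[str, int, int]]) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": genome.lengths[n]} for n in genome.names],
    }
    ref_id = {n: i for i, n in enumerate(genome.names)}
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for k, (chrom, s, e) in enumerate(intervals):
            a = pysam.AlignedSegment()
            a.query_name = f"feat_{k}"
            a.reference_id = ref_id[chrom]
            a.reference_start = s
            a.mapping_quality = 60
            a.cigarstring = f"{e - s}M"
            fh.write(a)
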