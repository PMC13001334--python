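"""Sequence-derived QC features for designed binders.

Why these features: in pooled CAR screens of designed 80-mers, failure is
often decided before any binding event — repetitive or GC-extreme DNA fails
synthesis, and lysine/glutamate-rich coding sequences (AAA/AAG/GAA/GAG
codons) disrupt translation through adenosine-dinucleotide runs and acidic
dipeptide repeats. The metrics here quantify those mechanisms directly from
the nucleotide and protein sequences: Shannon entropy (bits), GC content,
overlapping dinucleotide / dipeptide repeat counts, homopolymer runs, and
residue composition.
"""

from __future__ import annotations

import json
import math
import warnings
from collections import Counter
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGT")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
AA_ORDER = sorted(AA_ALPHABET)


class SequenceError(ValueError):
    """Raised for empty sequences or symbols outside the declared alphabet."""


def _validate(seq: str, alphabet: frozenset[str], what: str) -> str:
    if not seq:
        raise SequenceError(f"empty {what} sequence")
    bad = set(seq) - alphabet
    if bad:
        raise SequenceError(
            f"symbol(s) {sorted(bad)} outside the {what} alphabet"
        )
    return seq


def coerce_x_residues(aa_seq: str, replacement: str = "L") -> str:
    """Replace non-canonical 'X' residues, mirroring the common vendor
    convention of substituting an arbitrary residue before synthesis."""
    if replacement not in AA_ALPHABET:
        raise SequenceError(f"replacement {replacement!r} is not a canonical residue")
    return aa_seq.replace("X", replacement)


def shannon_entropy(seq: str, alphabet: Iterable[str] = DNA_ALPHABET) -> float:
    """Shannon entropy (bits) of the symbol frequency distribution.

    H = -sum_i p_i log2 p_i over observed symbol frequencies; bounded by
    log2 of the alphabet size. A homopolymer scores 0 bits; a sequence
    uniform over 4 nucleotides scores 2 bits.
    """
    alpha = frozenset(alphabet)
    _validate(seq, alpha, "input")
    n = len(seq)
    h = 0.0
    for count in Counter(seq).values():
        p = count / n
        h -= p * math.log2(p)
    return h


def gc_content(nt: str) -> float:
    """Fraction of G+C in an unambiguous DNA sequence.

    Ambiguity codes are rejected: a designed coding sequence submitted for
    synthesis is fully determined, so an ambiguous base signals a data error.
    """
    _validate(nt, DNA_ALPHABET, "DNA")
    return (nt.count("G") + nt.count("C")) / len(nt)


def overlapping_pair_count(seq: str, pair: str) -> int:
    """Count overlapping occurrences of a 2-symbol pattern.

    "AAAA" contains three overlapping "AA"; "EEE" contains two "EE".
    Overlap counting is the semantics used throughout the repeat features.
    """
    if len(pair) != 2:
        raise ValueError(f"pair must have length 2, got {pair!r}")
    return sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == pair)


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest single-symbol run (= len(seq) for constant strings)."""
    if not seq:
        return 0
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run > best:
            best = run
    return best


def aa_composition(aa_seq: str) -> dict[str, float]:
    """Per-residue fractions over the 20 canonical amino acids (sum to 1)."""
    _validate(aa_seq, AA_ALPHABET, "protein")
    n = len(aa_seq)
    counts = Counter(aa_seq)
    return {aa: counts.get(aa, 0) / n for aa in AA_ORDER}


def residues_in_runs(seq: str, symbol: str, min_run: int = 2) -> int:
    """Total count of `symbol` residues lying in runs of length >= min_run.

    Alternative "repeat" semantics to :func:`overlapping_pair_count`; exposed
    because published repeat counts do not always state which convention is
    used.
    """
    total = run = 0
    for ch in seq + "\x00":
        if ch == symbol:
            run += 1
        else:
            if run >= min_run:
                total += run
            run = 0
    return total


def kmer_entropy(seq: str, k: int) -> float:
    """Shannon entropy (bits) of the overlapping k-mer distribution."""
    if len(seq) < k:
        raise SequenceError(f"sequence shorter than k={k}")
    counts = Counter(seq[i : i + k] for i in range(len(seq) - k + 1))
    n = len(seq) - k + 1
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


# Column -> human-readable description; written alongside feature tables so
# downstream consumers get a machine-readable schema.
FEATURE_SCHEMA: dict[str, str] = {
    "design_id": "unique design identifier",
    "entropy_dna": "Shannon entropy of nucleotide frequencies (bits, max 2)",
    "entropy_protein": "Shannon entropy of residue frequencies (bits, max log2 20)",
    "entropy_dna_k2": "Shannon entropy of overlapping DNA 2-mers (bits)",
    "entropy_dna_k3": "Shannon entropy of overlapping DNA 3-mers (bits)",
    "entropy_protein_k2": "Shannon entropy of overlapping protein 2-mers (bits)",
    "gc_content": "fraction G+C in the coding DNA",
    "aa_dinucleotide_repeats": "overlapping 'AA' dinucleotide count in the DNA",
    "ee_repeats": "overlapping 'EE' dipeptide count in the protein",
    "e_run_residues": "glutamates lying in E-runs of length >= 2 (run semantics)",
    "max_homopolymer_dna": "longest single-nucleotide run",
    "max_homopolymer_protein": "longest single-residue run",
    "cys_count": "number of cysteines in the protein",
    **{f"comp_{aa}": f"fraction of residue {aa}" for aa in AA_ORDER},
    "helix_fraction": "fraction of residues labeled H (requires SS)",
    "ke_helix_ratio": "fraction of residues that are K/E and helical (requires SS)",
    "n_disulfides": "intra-chain disulfide pairs (requires 3D structure)",
}


def compute_feature_table(
    designs: Sequence,
    ss: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Compute the per-design feature panel.

    Parameters
    ----------
    designs
        Iterable of objects with ``design_id``, ``protein`` and ``dna``
        attributes (e.g. :class:`binderqc.simulate.DesignRecord`), or
        ``(design_id, protein, dna)`` tuples.
    ss
        Optional map design_id -> secondary-structure string over {H,E,C};
        when present, helix_fraction and ke_helix_ratio columns are filled.
        Records carrying their own ``ss`` attribute are used as fallback.

    Returns a DataFrame with one row per design and the columns documented
    in :data:`FEATURE_SCHEMA` (minus structure-only columns when no SS is
    available). A DNA/protein translation mismatch triggers a warning, not
    an error, so that vendor-side sequence edits do not halt a run.
    """
    from binderqc.structfeats import helix_fraction as _hf, ke_helix_ratio as _ke

    rows = []
    seen: set[str] = set()
    for d in designs:
        if isinstance(d, tuple):
            design_id, protein, dna = d[:3]
            rec_ss = None
        else:
            design_id, protein, dna = d.design_id, d.protein, d.dna
            rec_ss = getattr(d, "ss", None)
        if design_id in seen:
            raise ValueError(f"duplicate design_id {design_id!r}")
        seen.add(design_id)

        translated = str(Seq(dna).translate())
        if translated != protein:
            warnings.warn(
                f"{design_id}: DNA does not translate to the given protein",
                stacklevel=2,
            )
        comp = aa_composition(protein)
        row: dict[str, object] = {
            "design_id": design_id,
            "entropy_dna": shannon_entropy(dna, DNA_ALPHABET),
            "entropy_protein": shannon_entropy(protein, AA_ALPHABET),
            "entropy_dna_k2": kmer_entropy(dna, 2),
            "entropy_dna_k3": kmer_entropy(dna, 3),
            "entropy_protein_k2": kmer_entropy(protein, 2),
            "gc_content": gc_content(dna),
            "aa_dinucleotide_repeats": overlapping_pair_count(dna, "AA"),
            "ee_repeats": overlapping_pair_count(protein, "EE"),
            "e_run_residues": residues_in_runs(protein, "E"),
            "max_homopolymer_dna": max_homopolymer_run(dna),
            "max_homopolymer_protein": max_homopolymer_run(protein),
            "cys_count": protein.count("C"),
        }
        row.update({f"comp_{aa}": comp[aa] for aa in AA_ORDER})

        ss_string = None
        if ss is not None and design_id in ss:
            ss_string = ss[design_id]
        elif rec_ss:
            ss_string = rec_ss
        if ss_string is not None:
            row["helix_fraction"] = _hf(ss_string)
            row["ke_helix_ratio"] = _ke(protein, ss_string)
        rows.append(row)

    if not rows:
        return pd.DataFrame(columns=[c for c in FEATURE_SCHEMA if c != "n_disulfides"])
    return pd.DataFrame(rows)


def write_feature_schema(path) -> None:
    """Dump the feature-column schema as JSON next to a feature table."""
    with open(path, "w") as fh:
        json.dump(FEATURE_SCHEMA, fh, indent=2)
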