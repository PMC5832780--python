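"""Cross-haplotype conservation by exact sequence matching.

A query (mature or pre-miRNA) is conserved in a haplotype iff it occurs
somewhere in it with 100% identity over its full length, on either strand.
Under that criterion an exact substring search is equivalent to a BLAST
(megablast) search filtered to perfect full-length hits: any such BLAST hit
is an exact occurrence of the query or its reverse complement, and every
exact occurrence is found by the scan — so the alignment machinery adds
nothing and is not shipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_io import HaplotypeSequence, normalize_seq, revcomp


def _occurrences(needle: str, haystack: str) -> list[int]:
    out = []
    start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1  # overlapping occurrences count


def find_exact(query: str, hap: HaplotypeSequence) -> list[tuple[int, str]]:
    """All exact full-length occurrences of query (either strand) in hap.

    Returns (position, strand) pairs; positions are 0-based offsets of the
    match on the haplotype's forward sequence.  RNA queries (U) are
    normalised to DNA first.
    """
    q = normalize_seq(query, name="query")
    hits = [(p, "+") for p in _occurrences(q, hap.seq)]
    rc = revcomp(q)
    if rc != q:  # a palindromic query's '-' hits duplicate its '+' hits
        hits += [(p, "-") for p in _occurrences(rc, hap.seq)]
    return sorted(hits)


@dataclass
class PresenceMatrix:
    """Presence/absence of each query across haplotypes, with hit positions."""

    matrix: pd.DataFrame                 # bool, rows=query ids, cols=hap names
    hits: dict[tuple[str, str], list[tuple[int, str]]]

    def present(self, query_id: str, hap_name: str) -> bool:
        return bool(self.matrix.loc[query_id, hap_name])

    def to_tsv(self, path) -> None:
        out = self.matrix.replace({True: "present", False: "absent"})
        out.to_csv(path, sep="\t", index_label="query")


def presence_matrix(
    queries: list[tuple[str, str]], haps: list[HaplotypeSequence]
) -> PresenceMatrix:
    """Full presence/absence matrix; rows and columns keep input order.

    ``queries`` are (id, sequence) pairs; duplicate ids are rejected.
    """
    ids = [q[0] for q in queries]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate query ids: {dupes}")
    data = {}
    hits: dict[tuple[str, str], list[tuple[int, str]]] = {}
    for hap in haps:
        col = []
        for qid, qseq in queries:
            found = find_exact(qseq, hap)
            hits[(qid, hap.name)] = found
            col.append(bool(found))
        data[hap.name] = col
    matrix = pd.DataFrame(data, index=ids)
    return PresenceMatrix(matrix=matrix, hits=hits)


def conserved_locus_pairs(
    loci_a: list[tuple[str, str]], loci_b: list[tuple[str, str]]
) -> list[tuple[str, str]]:
    """Pairs (idA, idB) whose sequences match 100% over the shorter one.

    A pair is reported iff the shorter sequence occurs exactly (either
    strand) within the longer; a locus of A counts as conserved in B iff it
    has at least one partner.
    """
    pairs = []
    for ida, sa in loci_a:
        qa = normalize_seq(sa, name=ida)
        for idb, sb in loci_b:
            qb = normalize_seq(sb, name=idb)
            short, long_ = (qa, qb) if len(qa) <= len(qb) else (qb, qa)
            if short in long_ or revcomp(short) in long_:
                pairs.append((ida, idb))
    return pairs


def conserved_fraction(
    loci_a: list[tuple[str, str]], loci_b: list[tuple[str, str]]
) -> float:
    """Fraction of A loci with at least one 100%-identity partner in B."""
    if not loci_a:
        return 0.0
    pairs = conserved_locus_pairs(loci_a, loci_b)
    conserved = {ida for ida, _ in pairs}
    return len(conserved) / len(loci_a)
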