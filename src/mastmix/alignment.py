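"""DNA alignments and weighted site-pattern compression.

Characters are stored as IUPAC bitmasks over (A, C, G, T) so that gaps and
ambiguity codes become partial-uncertainty observations: the tip partial
vector is 1 on every compatible state.  Because sites are treated as
independent and identically distributed, identical columns can share one
likelihood computation weighted by multiplicity; ``PatternAlignment`` holds
that compressed form plus the map back to site order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO, AlignIO

logger = logging.getLogger(__name__)

# bit i set => state i is compatible (order A, C, G, T)
IUPAC_MASKS = {
    "A": 0b0001, "C": 0b0010, "G": 0b0100, "T": 0b1000,
    "U": 0b1000,
    "R": 0b0101, "Y": 0b1010, "S": 0b0110, "W": 0b1001,
    "K": 0b1100, "M": 0b0011,
    "B": 0b1110, "D": 0b1101, "H": 0b1011, "V": 0b0111,
    "N": 0b1111, "-": 0b1111, "?": 0b1111, ".": 0b1111, "X": 0b1111,
}
_MASK_TO_CHAR = {0b0001: "A", 0b0010: "C", 0b0100: "G", 0b1000: "T", 0b1111: "N"}
FULL_MASK = 0b1111


class AlignmentError(ValueError):
    pass


def _encode(seq: str, label: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.uint8)
    for i, ch in enumerate(seq.upper()):
        try:
            out[i] = IUPAC_MASKS[ch]
        except KeyError:
            raise AlignmentError(
                f"record '{label}': unrecognized character {ch!r} at column {i + 1}")
    return out


@dataclass
class Alignment:
    """A taxa x sites DNA alignment of IUPAC bitmask codes."""

    taxon_labels: list[str]
    data: np.ndarray  # uint8, (n_taxa, n_sites)

    def __post_init__(self):
        if len(self.taxon_labels) != len(set(self.taxon_labels)):
            dups = sorted({x for x in self.taxon_labels if self.taxon_labels.count(x) > 1})
            raise AlignmentError(f"duplicate taxon labels: {dups}")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxon_labels):
            raise AlignmentError("data shape does not match taxon labels")
        if self.n_sites < 1:
            raise AlignmentError("alignment has no sites")

    @classmethod
    def from_records(cls, records: list[tuple[str, str]]) -> "Alignment":
        if not records:
            raise AlignmentError("empty alignment: no sequence records")
        n = len(records[0][1])
        for label, seq in records:
            if len(seq) != n:
                raise AlignmentError(
                    f"record '{label}' has length {len(seq)}, expected {n}")
        labels = [r[0] for r in records]
        data = np.vstack([_encode(seq, label) for label, seq in records])
        return cls(taxon_labels=labels, data=data)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_labels)

    @property
    def n_sites(self) -> int:
        return int(self.data.shape[1])

    def drop_all_gap_columns(self) -> "Alignment":
        """Remove columns that carry no state information at any taxon."""
        informative = ~(self.data == FULL_MASK).all(axis=0)
        n_drop = int((~informative).sum())
        if n_drop:
            logger.info("excluding %d all-gap/unknown column(s)", n_drop)
            if not informative.any():
                raise AlignmentError("alignment consists entirely of gap columns")
            return Alignment(self.taxon_labels, self.data[:, informative])
        return self

    def to_fasta(self, path) -> None:
        lut = np.array([_MASK_TO_CHAR.get(m, "N") for m in range(16)])
        with open(path, "w") as fh:
            for i, label in enumerate(self.taxon_labels):
                fh.write(f">{label}\n")
                fh.write("".join(lut[self.data[i]]) + "\n")

    def subset_sites(self, idx) -> "Alignment":
        return Alignment(self.taxon_labels, self.data[:, idx])


@dataclass
class PatternAlignment:
    """Distinct site columns with multiplicities.

    ``patterns`` is (n_taxa, n_patterns); ``weights[p]`` counts how many
    alignment sites show pattern ``p``; ``site_to_pattern[i]`` recovers the
    pattern of site ``i`` so per-site quantities can be expanded.
    """

    taxon_labels: list[str]
    patterns: np.ndarray        # uint8, (n_taxa, n_patterns)
    weights: np.ndarray         # int64, (n_patterns,)
    site_to_pattern: np.ndarray  # int64, (n_sites,)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_labels)

    @property
    def n_patterns(self) -> int:
        return int(self.patterns.shape[1])

    @property
    def n_sites(self) -> int:
        return int(self.site_to_pattern.shape[0])

    def expand(self, per_pattern: np.ndarray) -> np.ndarray:
        """Expand a per-pattern vector/matrix (first axis) to per-site order."""
        return per_pattern[self.site_to_pattern]

    def tip_partials(self) -> np.ndarray:
        """(n_taxa, n_patterns, 4) float partial-likelihood vectors."""
        bits = np.array([1, 2, 4, 8], dtype=np.uint8)
        return ((self.patterns[:, :, None] & bits[None, None, :]) > 0).astype(float)


def compress_patterns(aln: Alignment) -> PatternAlignment:
    """Collapse identical columns; likelihoods downstream are unchanged."""
    cols = aln.data.T  # (n_sites, n_taxa)
    uniq, inverse, counts = np.unique(
        cols, axis=0, return_inverse=True, return_counts=True)
    return PatternAlignment(
        taxon_labels=list(aln.taxon_labels),
        patterns=uniq.T.copy(),
        weights=counts.astype(np.int64),
        site_to_pattern=inverse.astype(np.int64),
    )


# ---------------------------------------------------------------------------
# file readers


def read_alignment(path, format: str = "fasta") -> Alignment:
    """Read a DNA alignment from FASTA or relaxed sequential PHYLIP.

    Characters are upper-cased and U is mapped to T.  Columns that are gap
    or fully ambiguous in every taxon are excluded (with a log message),
    since they carry no likelihood information.
    """
    if format == "fasta":
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    elif format == "phylip":
        try:
            msa = AlignIO.read(str(path), "phylip-relaxed")
        except ValueError as e:
            raise AlignmentError(f"cannot parse PHYLIP file {path}: {e}") from e
        records = [(r.id, str(r.seq)) for r in msa]
    else:
        raise ValueError(f"unknown alignment format: {format!r}")
    aln = Alignment.from_records(records)
    return aln.drop_all_gap_columns()


def read_trees(path, required_tips=None, allow_duplicates: bool = False):
    """Read Newick trees, one per line, validating tip sets.

    Duplicate unrooted topologies are rejected by default because a mixture
    of identical topologies is not identifiable in its weights; pass
    ``allow_duplicates=True`` for deliberately degenerate model setups.
    """
    from .trees import TreeTopology, TreeError

    trees: list[TreeTopology] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            tree = TreeTopology.from_newick(line, rooted=False)
            if required_tips is not None:
                want = set(required_tips)
                got = set(tree.tip_labels)
                if got != want:
                    missing = sorted(want - got)
                    extra = sorted(got - want)
                    raise TreeError(
                        f"tree on line {lineno}: tip set mismatch "
                        f"(missing from tree: {missing}; not in alignment: {extra})")
            trees.append(tree)
    if not trees:
        raise TreeError(f"no trees found in {path}")
    if not allow_duplicates:
        seen: dict[str, int] = {}
        for i, t in enumerate(trees, start=1):
            cid = t.canonical_id()
            if cid in seen:
                raise TreeError(
                    f"trees on lines {seen[cid]} and {i} are the same unrooted "
                    "topology; duplicate topologies make the mixture weights "
                    "non-identifiable (use allow_duplicates to override)")
            seen[cid] = i
    return trees
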