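"""Substrate I/O, redundancy filtering, windowing, encoding and instance construction.

A calpain substrate is a protein sequence annotated with scissile-bond
positions.  Bond index ``i`` (1-based) denotes the peptide bond between
residue ``i`` (the P1 position) and residue ``i+1`` (P1').  Each substrate
additionally carries two per-residue structural tracks, produced upstream by
secondary-structure and solvent-accessibility predictors: a three-class
secondary-structure string over ``{H, E, C}`` and a two-class accessibility
string over ``{B, A}`` (below/above 25% relative accessibility).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import Align, SeqIO

#: The 20 standard amino acids in alphabetical order; one-hot block order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Secondary-structure classes: helix, sheet, other/coil.
SS_CLASSES = "HEC"
#: Solvent accessibility classes: Below / Above the 25% threshold.
SA_CLASSES = "BA"

#: Padding symbol used beyond sequence ends, per track.
PAD = {"sequence": "X", "ss": "C", "sa": "B"}

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_SS_INDEX = {a: i for i, a in enumerate(SS_CLASSES)}
_SA_INDEX = {a: i for i, a in enumerate(SA_CLASSES)}

CALPAIN_TYPES = ("calpain-1", "calpain-2", "calpain-3")


class ParseError(ValueError):
    """Raised on malformed input files; the message names the offending line."""


class ValidationError(ValueError):
    """Raised when annotations or tracks are inconsistent with the sequence."""


@dataclass(frozen=True)
class WindowSpec:
    """Extension lengths around a scissile bond.

    ``left`` counts P-side residues (…P3, P2, P1), ``right`` counts P'-side
    residues (P1', P2'…); the window covers ``left + right`` residues.
    """

    left: int
    right: int

    def __post_init__(self) -> None:
        if self.left < 0 or self.right < 0:
            raise ValueError("window extensions must be non-negative")
        if self.left + self.right < 1:
            raise ValueError("window must cover at least one residue")

    @property
    def width(self) -> int:
        return self.left + self.right

    @staticmethod
    def union(specs: "list[WindowSpec]") -> "WindowSpec":
        """Elementwise maximum: the narrowest window every spec fits inside."""
        return WindowSpec(
            max(s.left for s in specs), max(s.right for s in specs)
        )


@dataclass
class AnnotatedSubstrate:
    """A substrate sequence with cleavage annotations and structure tracks."""

    id: str
    residues: str
    ss_track: str
    sa_track: str
    cleavage_sites: list[int] = field(default_factory=list)
    calpain_types: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n = len(self.residues)
        if len(self.ss_track) != n or len(self.sa_track) != n:
            raise ValidationError(
                f"{self.id}: track lengths ({len(self.ss_track)}, "
                f"{len(self.sa_track)}) do not match sequence length {n}"
            )
        bad = set(self.residues) - set(AMINO_ACIDS + "X")
        if bad:
            raise ValidationError(f"{self.id}: invalid residues {sorted(bad)}")
        if set(self.ss_track) - set(SS_CLASSES):
            raise ValidationError(f"{self.id}: invalid secondary-structure labels")
        if set(self.sa_track) - set(SA_CLASSES):
            raise ValidationError(f"{self.id}: invalid accessibility labels")
        sites = self.cleavage_sites
        if any(not (1 <= s <= n - 1) for s in sites):
            raise ValidationError(
                f"{self.id}: cleavage site out of range (bond must be internal)"
            )
        if any(b <= a for a, b in zip(sites, sites[1:])):
            raise ValidationError(f"{self.id}: sites must be strictly increasing")
        if len(self.calpain_types) != len(sites):
            raise ValidationError(f"{self.id}: one type set required per site")

    def track(self, name: str) -> str:
        if name == "sequence":
            return self.residues
        if name == "ss":
            return self.ss_track
        if name == "sa":
            return self.sa_track
        raise KeyError(f"unknown track {name!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Instance:
    """A labeled multi-track window around a candidate scissile bond.

    Windows are cut at the union spec of all sub-kernels; each sub-kernel
    re-cuts its own narrower slice at evaluation time.
    """

    seq_window: str
    ss_window: str
    sa_window: str
    label: int
    source_id: str
    bond_index: int

    def window(self, track: str) -> str:
        return {"sequence": self.seq_window, "ss": self.ss_window,
                "sa": self.sa_window}[track]


@dataclass
class InstanceSet:
    """Result of instance construction: the instances plus build diagnostics."""

    instances: list[Instance]
    spec: WindowSpec
    warnings: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.instances)

    def __len__(self) -> int:
        return len(self.instances)

    @property
    def labels(self) -> np.ndarray:
        return np.array([i.label for i in self.instances], dtype=float)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _read_fasta_like(path, alphabet: str | None) -> list[tuple[str, str]]:
    with open(path) as fh:
        text = fh.read()
    stripped = [ln.strip() for ln in text.splitlines()]
    nonblank = [(i + 1, ln) for i, ln in enumerate(stripped) if ln]
    if not nonblank:
        raise ParseError(f"{path}: empty file (line 1)")
    first_line, first = nonblank[0]
    if not first.startswith(">"):
        raise ParseError(
            f"{path}: line {first_line}: expected FASTA header starting with '>'"
        )
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        if alphabet is not None:
            seq = "".join(c if c in alphabet else "X" for c in seq)
        records.append((rec.id, seq))
    return records


def read_fasta(path) -> list[tuple[str, str]]:
    """Read protein sequences; uppercase, non-standard symbols mapped to 'X'."""
    return _read_fasta_like(path, AMINO_ACIDS)


def read_track_file(path) -> dict[str, str]:
    """Read a FASTA-like per-residue label track file (SS or SA)."""
    return dict(_read_fasta_like(path, None))


def read_annotations(path) -> dict[str, list[tuple[int, frozenset[str]]]]:
    """Read the cleavage-site TSV: ``id<TAB>bond_index<TAB>type[,type...]``.

    The calpain-type field is optional; ``-`` or absence means unlabeled
    (empty type set).  Returns sites grouped by sequence id, in file order.
    """
    sites: dict[str, list[tuple[int, frozenset[str]]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}: line {lineno}: expected id<TAB>bond_index")
            seq_id = parts[0].strip()
            try:
                bond = int(parts[1])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: bond index {parts[1]!r} is not an integer"
                ) from None
            types: frozenset[str] = frozenset()
            if len(parts) >= 3 and parts[2].strip() not in ("", "-"):
                names = [t.strip() for t in parts[2].split(",")]
                unknown = [t for t in names if t not in CALPAIN_TYPES]
                if unknown:
                    raise ParseError(
                        f"{path}: line {lineno}: unknown calpain type {unknown[0]!r}"
                    )
                types = frozenset(names)
            sites.setdefault(seq_id, []).append((bond, types))
    return sites


def load_substrates(fasta_path, annotation_path=None, ss_path=None,
                    sa_path=None) -> list[AnnotatedSubstrate]:
    """Assemble fully validated substrates from FASTA + TSV + track files.

    Missing track files yield all-coil / all-buried tracks (useful when only
    sequence-based kernels are in play); a missing annotation file yields
    unannotated substrates (scan-only use).
    """
    seqs = read_fasta(fasta_path)
    ann = read_annotations(annotation_path) if annotation_path else {}
    ss = read_track_file(ss_path) if ss_path else {}
    sa = read_track_file(sa_path) if sa_path else {}
    known = {sid for sid, _ in seqs}
    for sid in ann:
        if sid not in known:
            raise ValidationError(f"annotated id {sid!r} not present in FASTA")
    out = []
    for sid, residues in seqs:
        n = len(residues)
        pairs = sorted(ann.get(sid, []), key=lambda p: p[0])
        bonds = [b for b, _ in pairs]
        if len(set(bonds)) != len(bonds):
            raise ValidationError(f"{sid}: duplicate cleavage site")
        out.append(AnnotatedSubstrate(
            id=sid,
            residues=residues,
            ss_track=ss.get(sid, "C" * n),
            sa_track=sa.get(sid, "B" * n),
            cleavage_sites=bonds,
            calpain_types=[t for _, t in pairs],
        ))
    return out


# ---------------------------------------------------------------------------
# Redundancy filtering
# ---------------------------------------------------------------------------

_ALIGNER = Align.PairwiseAligner(
    mode="global", match_score=1, mismatch_score=0, gap_score=-1
)


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment length (match=1,
    mismatch=0, gap=-1 scoring)."""
    aln = _ALIGNER.align(a, b)[0]
    return aln.counts().identities / aln.length


def remove_redundant(substrates: list[AnnotatedSubstrate],
                     identity_threshold: float = 0.95) -> list[AnnotatedSubstrate]:
    """Greedy redundancy filter addressing selection bias in curated sets.

    Substrates are processed in input order; one is kept only if its identity
    to every already-kept substrate is <= the threshold.  Deterministic given
    input order, and idempotent.
    """
    if not (0 < identity_threshold <= 1):
        raise ValueError("identity threshold must be in (0, 1]")
    kept: list[AnnotatedSubstrate] = []
    for sub in substrates:
        if all(pairwise_identity(sub.residues, k.residues) <= identity_threshold
               for k in kept):
            kept.append(sub)
    return kept


# ---------------------------------------------------------------------------
# Windows and encoding
# ---------------------------------------------------------------------------

def extract_window(substrate: AnnotatedSubstrate, bond_index: int,
                   spec: WindowSpec, track: str = "sequence") -> str:
    """Cut the (left, right) window around a bond from the named track.

    Covers residues ``bond-left+1 .. bond`` and ``bond+1 .. bond+right``;
    positions beyond the sequence ends are padded with the track's neutral
    symbol ('X' sequence, 'C' coil, 'B' buried).
    """
    return cut_window(substrate.track(track), bond_index, spec, PAD[track])


def cut_window(chars: str, bond_index: int, spec: WindowSpec, pad: str) -> str:
    n = len(chars)
    out = []
    for pos in range(bond_index - spec.left + 1, bond_index + spec.right + 1):
        out.append(chars[pos - 1] if 1 <= pos <= n else pad)
    return "".join(out)


def recut(window: str, stored: WindowSpec, spec: WindowSpec) -> str:
    """Re-cut a narrower window from one stored at the union spec."""
    if spec.left > stored.left or spec.right > stored.right:
        raise ValueError(
            f"requested window {spec} wider than stored {stored}"
        )
    return window[stored.left - spec.left: stored.left + spec.right]


_TRACK_INDEX = {"sequence": _AA_INDEX, "ss": _SS_INDEX, "sa": _SA_INDEX}


def binary_encode(window: str, track: str = "sequence") -> np.ndarray:
    """Canonical one-hot encoding: each position becomes an alphabet-sized
    binary block ('X' encodes as an all-zero block)."""
    index = _TRACK_INDEX[track]
    width = len(index)
    vec = np.zeros(width * len(window))
    for i, c in enumerate(window):
        if c == "X":
            continue
        try:
            vec[width * i + index[c]] = 1.0
        except KeyError:
            raise ValueError(f"invalid character {c!r} for track {track!r}") from None
    return vec


# ---------------------------------------------------------------------------
# Instance construction
# ---------------------------------------------------------------------------

def _make_instance(sub: AnnotatedSubstrate, bond: int, spec: WindowSpec,
                   label: int) -> Instance:
    return Instance(
        seq_window=extract_window(sub, bond, spec, "sequence"),
        ss_window=extract_window(sub, bond, spec, "ss"),
        sa_window=extract_window(sub, bond, spec, "sa"),
        label=label,
        source_id=sub.id,
        bond_index=bond,
    )


def build_instances(substrates: list[AnnotatedSubstrate], max_spec: WindowSpec,
                    neg_ratio: int = 10, rng_seed: int = 0) -> InstanceSet:
    """Build the labeled training set: every annotated site is a positive;
    negatives are sampled uniformly without replacement from the pool of all
    other internal bonds across all substrates, at ``neg_ratio`` negatives
    per positive (the 10:1 convention by default)."""
    if neg_ratio < 1:
        raise ValueError("neg_ratio must be >= 1")
    positives: list[Instance] = []
    pool: list[tuple[int, int]] = []  # (substrate idx, bond)
    for si, sub in enumerate(substrates):
        annotated = set(sub.cleavage_sites)
        for bond in sub.cleavage_sites:
            positives.append(_make_instance(sub, bond, max_spec, +1))
        for bond in range(1, len(sub)):
            if bond not in annotated:
                pool.append((si, bond))
    warnings: list[str] = []
    n_neg = neg_ratio * len(positives)
    rng = np.random.default_rng(rng_seed)
    if n_neg > len(pool):
        warnings.append(
            f"only {len(pool)} candidate bonds available for {n_neg} "
            "requested negatives; emitting all"
        )
        chosen = np.arange(len(pool))
    else:
        chosen = rng.choice(len(pool), size=n_neg, replace=False)
    negatives = [_make_instance(substrates[pool[i][0]], pool[i][1], max_spec, -1)
                 for i in chosen]
    return InstanceSet(positives + negatives, max_spec, warnings)


def partition_by_calpain_type(substrates: list[AnnotatedSubstrate],
                              calpain_type: str = "all") -> list[AnnotatedSubstrate]:
    """Subset substrates by the calpain isoform that cleaves them.

    For a specific isoform, keeps substrates with at least one matching site
    and retains only the matching sites; per-type counts may overlap because
    some substrates are cleaved by more than one isoform.
    """
    if calpain_type == "all":
        return list(substrates)
    if calpain_type not in CALPAIN_TYPES:
        raise ValueError(f"unknown calpain type {calpain_type!r}")
    out = []
    for sub in substrates:
        keep = [(b, t) for b, t in zip(sub.cleavage_sites, sub.calpain_types)
                if calpain_type in t]
        if keep:
            out.append(AnnotatedSubstrate(
                id=sub.id, residues=sub.residues, ss_track=sub.ss_track,
                sa_track=sub.sa_track,
                cleavage_sites=[b for b, _ in keep],
                calpain_types=[t for _, t in keep],
            ))
    return out
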