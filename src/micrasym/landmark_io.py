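"""I/O for the file formats the pipeline touches.

TPS landmark files (tpsDig flavour: ``LM=``, optional ``ID=``, ``IMAGE=``,
``SCALE=`` records), Newick trees, FASTA/relaxed-PHYLIP alignments, and CSV
result tables.  Also provides landmark-subset extraction, used to carve the
terminal-lobule blocks (landmarks 1-7 and 9-15) out of the 15-landmark
configurations.

Specimen metadata travel in the TPS ``ID=`` string using the convention
``<species>_<specimen>_r<replicate>`` (underscore-delimited, parsed from the
right), since TPS has no standard species/replicate fields.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
from Bio import AlignIO, SeqIO


class TpsParseError(ValueError):
    """Raised when a TPS record is malformed."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One digitization (replicate) of one structure of one specimen."""

    specimen_id: str
    species_id: str
    replicate: int
    coords: np.ndarray  # (k, 2) float array

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be a (k, 2) array")
        if coords.shape[0] < 3:
            raise ValueError("a landmark configuration needs k >= 3 landmarks")
        if not np.all(np.isfinite(coords)):
            raise ValueError("landmark coordinates must be finite")
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")
        object.__setattr__(self, "coords", coords)

    @property
    def k(self) -> int:
        return self.coords.shape[0]


@dataclass
class LandmarkDataset:
    """A set of digitized landmark configurations sharing one scheme."""

    records: list[SpecimenRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("dataset must contain at least one record")
        ks = {r.k for r in self.records}
        if len(ks) != 1:
            raise ValueError(f"all records must share one landmark count, got {sorted(ks)}")
        seen = set()
        for r in self.records:
            key = (r.specimen_id, r.replicate)
            if key in seen:
                raise ValueError(f"duplicate (specimen, replicate): {key}")
            seen.add(key)

    @property
    def k(self) -> int:
        return self.records[0].k

    @property
    def species(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.species_id not in out:
                out.append(r.species_id)
        return out

    @property
    def specimen_ids(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.specimen_id not in out:
                out.append(r.specimen_id)
        return out

    def replicate_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.specimen_id] = counts.get(r.specimen_id, 0) + 1
        return counts

    @property
    def is_balanced(self) -> bool:
        return len(set(self.replicate_counts().values())) == 1

    @property
    def n_replicates(self) -> int:
        counts = self.replicate_counts()
        if len(set(counts.values())) != 1:
            raise ValueError("design is unbalanced; no single replicate count")
        return next(iter(counts.values()))

    def coords_array(self) -> np.ndarray:
        """All configurations stacked as an (n_records, k, 2) array."""
        return np.stack([r.coords for r in self.records])

    def subset_species(self, species: Iterable[str]) -> "LandmarkDataset":
        wanted = set(species)
        unknown = wanted - set(self.species)
        if unknown:
            raise ValueError(f"unknown species: {sorted(unknown)}")
        return LandmarkDataset([r for r in self.records if r.species_id in wanted])

    def design_summary(self) -> dict:
        counts = self.replicate_counts()
        per_species: dict[str, set] = {}
        for r in self.records:
            per_species.setdefault(r.species_id, set()).add(r.specimen_id)
        return {
            "k": self.k,
            "n_species": len(per_species),
            "n_specimens": len(counts),
            "specimens_per_species": {s: len(v) for s, v in per_species.items()},
            "balanced": self.is_balanced,
        }


@dataclass(frozen=True)
class AlignmentSummary:
    n_sequences: int
    length: int
    n_variable: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_variable <= self.length:
            raise ValueError("0 <= n_variable <= length violated")


_ID_RE = re.compile(r"^(?P<species>.+)_(?P<specimen>[^_]+)_r?(?P<rep>\d+)$")


def parse_specimen_id(id_string: str) -> tuple[str, str, int]:
    """Split ``<species>_<specimen>_r<replicate>`` from the right.

    The species part may itself contain underscores; the last two fields are
    the specimen token and the replicate index (optionally prefixed ``r``).
    """
    m = _ID_RE.match(id_string.strip())
    if not m:
        raise TpsParseError(
            f"cannot parse ID string {id_string!r}; expected '<species>_<specimen>_r<replicate>'"
        )
    species = m.group("species")
    specimen = f"{species}_{m.group('specimen')}"
    return specimen, species, int(m.group("rep"))


def read_tps(path, manifest: dict[str, tuple[str, str, int]] | None = None) -> LandmarkDataset:
    """Parse a TPS landmark file into a :class:`LandmarkDataset`.

    Each record starts with ``LM=k`` followed by ``k`` coordinate lines and
    optional ``ID=``, ``IMAGE=``, ``SCALE=`` lines.  ``SCALE=`` multiplies the
    coordinates.  Specimen/species/replicate come from the ID string (or from
    ``manifest``, a mapping ID -> (specimen_id, species_id, replicate)).
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        text = Path(path).read_text()
    records: list[SpecimenRecord] = []
    lines = text.splitlines()
    i = 0
    rec_no = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if not line.upper().startswith("LM="):
            raise TpsParseError(f"expected 'LM=' at line {i}, got {line!r}")
        rec_no += 1
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TpsParseError(f"record {rec_no}: bad LM count {line!r}") from exc
        coords = np.empty((k, 2), dtype=float)
        for j in range(k):
            if i >= len(lines) or "=" in lines[i]:
                raise TpsParseError(
                    f"record {rec_no}: expected {k} coordinate lines, found {j}"
                )
            parts = lines[i].split()
            if len(parts) != 2:
                raise TpsParseError(
                    f"record {rec_no}: bad coordinate line {lines[i]!r}"
                )
            try:
                coords[j] = [float(parts[0]), float(parts[1])]
            except ValueError as exc:
                raise TpsParseError(
                    f"record {rec_no}: non-numeric coordinate {lines[i]!r}"
                ) from exc
            i += 1
        id_string = None
        scale = None
        while i < len(lines):
            stripped = lines[i].strip()
            if not stripped:
                i += 1
                continue
            upper = stripped.upper()
            if upper.startswith("LM="):
                break
            if upper.startswith("ID="):
                id_string = stripped.split("=", 1)[1]
            elif upper.startswith("SCALE="):
                try:
                    scale = float(stripped.split("=", 1)[1])
                except ValueError as exc:
                    raise TpsParseError(
                        f"record {rec_no}: non-numeric SCALE {stripped!r}"
                    ) from exc
            elif upper.startswith("IMAGE="):
                pass  # ignored; images are out of scope
            else:
                raise TpsParseError(f"record {rec_no}: unrecognized line {stripped!r}")
            i += 1
        if scale is not None:
            coords = coords * scale
        if id_string is None:
            id_string = f"unknown_sp{rec_no:04d}_r1"
        if manifest is not None and id_string in manifest:
            specimen, species, rep = manifest[id_string]
        else:
            specimen, species, rep = parse_specimen_id(id_string)
        records.append(SpecimenRecord(specimen, species, rep, coords))
    if not records:
        raise TpsParseError("no TPS records found")
    return LandmarkDataset(records)


def write_tps(dataset: LandmarkDataset, path, decimals: int = 6) -> None:
    """Write a dataset as TPS; ``read_tps`` round-trips it (to `decimals`)."""
    buf = io.StringIO()
    for rec in dataset.records:
        buf.write(f"LM={rec.k}\n")
        for x, y in rec.coords:
            buf.write(f"{x:.{decimals}f} {y:.{decimals}f}\n")
        # ID encodes "<species>_<specimen token>_r<replicate>"
        token = rec.specimen_id
        if token.startswith(rec.species_id + "_"):
            token = token[len(rec.species_id) + 1:]
        buf.write(f"ID={rec.species_id}_{token}_r{rec.replicate}\n")
    if hasattr(path, "write"):
        path.write(buf.getvalue())
    else:
        Path(path).write_text(buf.getvalue())


def read_newick(source) -> dendropy.Tree:
    """Read a rooted Newick tree (path or string) with branch lengths.

    Tip labels must be unique; negative branch lengths are rejected.
    """
    if isinstance(source, dendropy.Tree):
        tree = source
    else:
        text = None
        if isinstance(source, (str, bytes)) and "(" in str(source):
            text = str(source)
        elif hasattr(source, "read"):
            text = source.read()
        else:
            text = Path(source).read_text()
        tree = dendropy.Tree.get(data=text, schema="newick")
    labels = [t.label for t in tree.taxon_namespace]
    if len(labels) != len(set(labels)):
        raise ValueError("tip labels are not unique")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length on edge to {edge.head_node}")
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    text = tree.as_string(schema="newick", suppress_rooting=True)
    Path(path).write_text(text)


def summarize_alignment(
    path,
    fmt: str = "fasta",
    count_gaps: bool = False,
    ambiguous_distinct: bool = False,
) -> AlignmentSummary:
    """Column statistics of a multiple sequence alignment.

    A column is *variable* when it holds >= 2 distinct states.  By default a
    gap ('-' or '.') is not a state and IUPAC ambiguity codes are reduced to
    'N' (i.e. not counted as distinct from each other); both behaviours can
    be switched with the flags, since digitized datasets differ in their
    conventions.
    """
    aln = AlignIO.read(path, fmt)
    lengths = {len(rec.seq) for rec in aln}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: sequences differ in length")
    length = lengths.pop()
    plain = {"A", "C", "G", "T", "U"}
    n_variable = 0
    for col in range(length):
        states = set()
        for rec in aln:
            c = str(rec.seq[col]).upper()
            if c in "-.":
                if count_gaps:
                    states.add("-")
                continue
            if c not in plain and not ambiguous_distinct:
                c = "N"
            states.add(c)
        if len(states) >= 2:
            n_variable += 1
    return AlignmentSummary(n_sequences=len(aln), length=length, n_variable=n_variable)


def extract_landmarks(dataset: LandmarkDataset, indices: Sequence[int]) -> LandmarkDataset:
    """Restrict every configuration to `indices` (1-based), relabelled 1..m.

    Used for the terminal-lobule analyses: landmarks 1-7 (lower sublobe) and
    9-15 (upper sublobe) of the 15-landmark scheme.
    """
    idx = list(indices)
    if len(set(idx)) != len(idx):
        raise ValueError("duplicate landmark indices")
    k = dataset.k
    for i in idx:
        if not 1 <= i <= k:
            raise ValueError(f"landmark index {i} out of range 1..{k}")
    sel = np.asarray(idx, dtype=int) - 1
    return LandmarkDataset(
        [
            SpecimenRecord(r.specimen_id, r.species_id, r.replicate, r.coords[sel])
            for r in dataset.records
        ]
    )
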