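"""Genotype panel I/O, QC and marker-map handling.

Supports the PLINK text (PED/MAP) and binary (BED/BIM/FAM, SNP-major) dialects
plus a plain TSV dosage matrix. Genotypes are stored as coded-allele dosages in
{0, 1, 2} with ``MISSING`` (-1) as the single missing sentinel, preserved
through every reader and writer.

Coordinates follow the BIM convention: physical positions are 1-based base
pairs; genetic positions are stored internally in Morgans (MAP/BIM files carry
centiMorgans and are converted on the way in/out).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

MISSING = -1

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


class PanelFormatError(ValueError):
    """A genotype file could not be parsed."""


def _chrom_key(c: str):
    """Sort key placing numeric chromosome labels first, in numeric order."""
    try:
        return (0, int(c), "")
    except ValueError:
        return (1, 0, str(c))


@dataclass
class MarkerMap:
    """Per-marker map: chromosome, physical (bp) and genetic (Morgan) position.

    ``bp`` is 1-based; ``gpos`` is in Morgans and may be all-zero when the
    source file carried no genetic distances (use :func:`assign_gpos`).
    """

    chrom: np.ndarray
    bp: np.ndarray
    gpos: np.ndarray
    marker_id: np.ndarray
    coded_allele: np.ndarray
    other_allele: np.ndarray

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.bp = np.asarray(self.bp, dtype=np.int64)
        self.gpos = np.asarray(self.gpos, dtype=np.float64)
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.coded_allele = np.asarray(self.coded_allele, dtype=object)
        self.other_allele = np.asarray(self.other_allele, dtype=object)
        n = len(self.marker_id)
        for name in ("chrom", "bp", "gpos", "coded_allele", "other_allele"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"MarkerMap field {name!r} length mismatch")
        ids, counts = np.unique(self.marker_id.astype(str), return_counts=True)
        if np.any(counts > 1):
            dup = ids[counts > 1][0]
            raise PanelFormatError(f"duplicate marker id {dup!r}")
        if np.any(self.gpos < 0):
            raise ValueError("genetic positions must be non-negative")

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    def chromosomes(self) -> list:
        """Chromosome labels in order of first appearance."""
        seen, out = set(), []
        for c in self.chrom:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out

    def chrom_slices(self) -> list[tuple[object, slice]]:
        """Contiguous (chromosome, slice) blocks in map order."""
        out = []
        start = 0
        for i in range(1, self.n_markers + 1):
            if i == self.n_markers or self.chrom[i] != self.chrom[start]:
                out.append((self.chrom[start], slice(start, i)))
                start = i
        return out

    def sort_order(self) -> np.ndarray:
        keys = [( _chrom_key(c), b) for c, b in zip(self.chrom, self.bp)]
        return np.array(sorted(range(self.n_markers), key=keys.__getitem__),
                        dtype=np.int64)

    def take(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.chrom[idx], self.bp[idx], self.gpos[idx],
                         self.marker_id[idx], self.coded_allele[idx],
                         self.other_allele[idx])

    def validate_sorted(self):
        for chrom, sl in self.chrom_slices():
            bp = self.bp[sl]
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"bp not strictly increasing on chromosome {chrom}")
            if np.any(np.diff(self.gpos[sl]) < 0):
                raise ValueError(f"gpos decreasing on chromosome {chrom}")


@dataclass
class GenotypePanel:
    """Individuals x markers dosage matrix with its marker map and labels.

    ``G[i, j]`` is the count of ``markers.coded_allele[j]`` carried by sample
    ``i`` (0, 1, 2) or ``MISSING``.
    """

    markers: MarkerMap
    sample_ids: list
    G: np.ndarray
    groups: list | None = None

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=np.int8)
        if self.G.shape != (len(self.sample_ids), self.markers.n_markers):
            raise ValueError("G shape does not match samples x markers")
        valid = np.isin(self.G, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("genotypes must be in {0,1,2} or MISSING")
        if self.groups is not None and len(self.groups) != len(self.sample_ids):
            raise ValueError("groups length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return self.markers.n_markers

    def sort_markers(self) -> "GenotypePanel":
        order = self.markers.sort_order()
        return GenotypePanel(self.markers.take(order), list(self.sample_ids),
                             self.G[:, order], self.groups)


@dataclass
class AlleleFrequencies:
    """Per-marker coded-allele frequency and non-missing call count."""

    p: np.ndarray
    n_obs: np.ndarray

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=np.float64)
        self.n_obs = np.asarray(self.n_obs, dtype=np.int64)
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("allele frequencies must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_map_file(path: str) -> MarkerMap:
    chroms, ids, gpos, bps = [], [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise PanelFormatError(f"{path}: line {ln}: expected 4 columns")
            chroms.append(parts[0])
            ids.append(parts[1])
            gpos.append(float(parts[2]) / 100.0)  # cM -> Morgans
            bps.append(int(parts[3]))
    n = len(ids)
    return MarkerMap(np.array(chroms, dtype=object), np.array(bps),
                     np.array(gpos), np.array(ids, dtype=object),
                     np.full(n, "0", dtype=object), np.full(n, "0", dtype=object))


def _read_ped(prefix: str) -> GenotypePanel:
    mmap = _read_map_file(prefix + ".map")
    m = mmap.n_markers
    sample_ids, groups, rows = [], [], []
    with open(prefix + ".ped") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise PanelFormatError(
                    f"{prefix}.ped: line {ln}: expected {6 + 2 * m} fields, got {len(parts)}")
            groups.append(parts[0])
            sample_ids.append(parts[1])
            rows.append(parts[6:])
    alleles = np.array(rows, dtype=object).reshape(len(rows), m, 2)
    coded = np.empty(m, dtype=object)
    other = np.empty(m, dtype=object)
    G = np.full((len(rows), m), MISSING, dtype=np.int8)
    for j in range(m):
        obs = alleles[:, j, :]
        symbols = sorted(set(obs.ravel()) - {"0"})
        if len(symbols) > 2:
            raise PanelFormatError(
                f"{prefix}.ped: marker {mmap.marker_id[j]!r} has >2 alleles")
        coded[j] = symbols[0] if symbols else "0"
        other[j] = symbols[1] if len(symbols) > 1 else "0"
        called = (obs != "0").all(axis=1)
        G[called, j] = (obs[called] == coded[j]).sum(axis=1)
    mmap = replace(mmap, coded_allele=coded, other_allele=other)
    groups_out = None if all(g == "0" for g in groups) else groups
    return GenotypePanel(mmap, sample_ids, G, groups_out).sort_markers()


def _write_ped(panel: GenotypePanel, prefix: str):
    mmap = panel.markers
    with open(prefix + ".map", "w") as fh:
        for j in range(mmap.n_markers):
            fh.write(f"{mmap.chrom[j]}\t{mmap.marker_id[j]}\t"
                     f"{mmap.gpos[j] * 100.0:.8g}\t{mmap.bp[j]}\n")
    with open(prefix + ".ped", "w") as fh:
        for i, sid in enumerate(panel.sample_ids):
            fid = panel.groups[i] if panel.groups is not None else "0"
            fields = [str(fid), str(sid), "0", "0", "0", "-9"]
            for j in range(mmap.n_markers):
                g = panel.G[i, j]
                a, b = mmap.coded_allele[j], mmap.other_allele[j]
                pair = {2: (a, a), 1: (a, b), 0: (b, b)}.get(int(g), ("0", "0"))
                fields.extend(pair)
            fh.write(" ".join(fields) + "\n")


def _read_bed(prefix: str) -> GenotypePanel:
    mmap_rows = []
    with open(prefix + ".bim") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6:
                raise PanelFormatError(f"{prefix}.bim: line {ln}: expected 6 columns")
            mmap_rows.append(parts)
    chroms = np.array([r[0] for r in mmap_rows], dtype=object)
    ids = np.array([r[1] for r in mmap_rows], dtype=object)
    gpos = np.array([float(r[2]) / 100.0 for r in mmap_rows])
    bps = np.array([int(r[3]) for r in mmap_rows])
    a1 = np.array([r[4] for r in mmap_rows], dtype=object)
    a2 = np.array([r[5] for r in mmap_rows], dtype=object)
    mmap = MarkerMap(chroms, bps, gpos, ids, a1, a2)

    sample_ids, groups = [], []
    with open(prefix + ".fam") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) < 2:
                raise PanelFormatError(f"{prefix}.fam: line {ln}: expected >=2 columns")
            groups.append(parts[0])
            sample_ids.append(parts[1])
    n, m = len(sample_ids), mmap.n_markers

    with open(prefix + ".bed", "rb") as fh:
        raw = fh.read()
    if raw[:3] != _BED_MAGIC:
        raise PanelFormatError(f"{prefix}.bed: bad magic bytes (not a SNP-major BED file)")
    bpm = (n + 3) // 4  # bytes per marker
    if len(raw) != 3 + bpm * m:
        raise PanelFormatError(f"{prefix}.bed: unexpected file size")
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bpm)
    # 2-bit codes, sample i at bits (2*(i%4)): 00 hom-A1, 01 missing, 10 het, 11 hom-A2
    shifts = (2 * (np.arange(n) % 4)).astype(np.uint8)
    codes = (data[:, np.arange(n) // 4] >> shifts) & 0b11  # (m, n)
    lut = np.array([2, MISSING, 1, 0], dtype=np.int8)
    G = lut[codes].T
    groups_out = None if all(g == "0" for g in groups) else groups
    return GenotypePanel(mmap, sample_ids, G, groups_out).sort_markers()


def _write_bed(panel: GenotypePanel, prefix: str):
    mmap = panel.markers
    with open(prefix + ".bim", "w") as fh:
        for j in range(mmap.n_markers):
            fh.write(f"{mmap.chrom[j]}\t{mmap.marker_id[j]}\t"
                     f"{mmap.gpos[j] * 100.0:.8g}\t{mmap.bp[j]}\t"
                     f"{mmap.coded_allele[j]}\t{mmap.other_allele[j]}\n")
    with open(prefix + ".fam", "w") as fh:
        for i, sid in enumerate(panel.sample_ids):
            fid = panel.groups[i] if panel.groups is not None else "0"
            fh.write(f"{fid} {sid} 0 0 0 -9\n")
    n, m = panel.n_samples, panel.n_markers
    inv = np.zeros(4, dtype=np.uint8)
    inv[[2, 1, 0]] = [0b00, 0b10, 0b11]
    codes = np.where(panel.G.T == MISSING, 0b01, inv[np.clip(panel.G.T, 0, 2)])
    bpm = (n + 3) // 4
    out = np.zeros((m, bpm), dtype=np.uint8)
    for i in range(n):
        out[:, i // 4] |= (codes[:, i].astype(np.uint8) << np.uint8(2 * (i % 4)))
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(out.tobytes())


def _read_tsv(prefix: str) -> GenotypePanel:
    mmap = _read_map_file(prefix + ".map")
    sample_ids, rows = [], []
    with open(prefix + ".tsv") as fh:
        header = fh.readline().split("\t")
        ids = [h.strip() for h in header[1:]]
        if [str(x) for x in mmap.marker_id] != ids:
            raise PanelFormatError(f"{prefix}.tsv: header marker ids do not match {prefix}.map")
        for ln, line in enumerate(fh, 2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 1 + mmap.n_markers:
                raise PanelFormatError(f"{prefix}.tsv: line {ln}: wrong column count")
            sample_ids.append(parts[0])
            rows.append([MISSING if p in ("NA", ".", "") else int(p) for p in parts[1:]])
    n = mmap.n_markers
    mmap = replace(mmap, coded_allele=np.full(n, "A", dtype=object),
                   other_allele=np.full(n, "B", dtype=object))
    return GenotypePanel(mmap, sample_ids, np.array(rows, dtype=np.int8)).sort_markers()


def _write_tsv(panel: GenotypePanel, prefix: str):
    mmap = panel.markers
    with open(prefix + ".map", "w") as fh:
        for j in range(mmap.n_markers):
            fh.write(f"{mmap.chrom[j]}\t{mmap.marker_id[j]}\t"
                     f"{mmap.gpos[j] * 100.0:.8g}\t{mmap.bp[j]}\n")
    with open(prefix + ".tsv", "w") as fh:
        fh.write("sample_id\t" + "\t".join(str(x) for x in mmap.marker_id) + "\n")
        for i, sid in enumerate(panel.sample_ids):
            vals = ["NA" if g == MISSING else str(int(g)) for g in panel.G[i]]
            fh.write(str(sid) + "\t" + "\t".join(vals) + "\n")


_READERS = {"ped": _read_ped, "bed": _read_bed, "tsv": _read_tsv}
_WRITERS = {"ped": _write_ped, "bed": _write_bed, "tsv": _write_tsv}
_SUFFIXES = {"ped": (".ped", ".map"), "bed": (".bed", ".bim", ".fam"),
             "tsv": (".tsv", ".map")}


def read_panel(path_prefix: str, dialect: str = "bed") -> GenotypePanel:
    """Read a genotype panel; markers come back sorted by (chrom, bp)."""
    if dialect not in _READERS:
        raise ValueError(f"unknown dialect {dialect!r}; expected ped, bed or tsv")
    for suf in _SUFFIXES[dialect]:
        if not os.path.exists(path_prefix + suf):
            raise FileNotFoundError(f"expected file {path_prefix + suf} not found")
    return _READERS[dialect](path_prefix)


def write_panel(panel: GenotypePanel, path_prefix: str, dialect: str = "bed"):
    if dialect not in _WRITERS:
        raise ValueError(f"unknown dialect {dialect!r}; expected ped, bed or tsv")
    _WRITERS[dialect](panel, path_prefix)


def read_group_labels(path: str) -> dict:
    """Two-column TSV (sample_id, group) -> dict."""
    out = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 2:
                raise PanelFormatError(f"{path}: line {ln}: expected 2 columns")
            out[parts[0]] = parts[1]
    return out


# ---------------------------------------------------------------------------
# QC and derived quantities
# ---------------------------------------------------------------------------

def filter_call_rate(panel: GenotypePanel,
                     min_call_rate: float = 0.95) -> tuple[GenotypePanel, int]:
    """Drop markers whose fraction of non-missing genotypes is below threshold.

    Returns the filtered panel and the number of markers removed. Samples are
    never touched.
    """
    if not 0 < min_call_rate <= 1:
        raise ValueError("min_call_rate must be in (0, 1]")
    call_rate = (panel.G != MISSING).mean(axis=0)
    keep = call_rate >= min_call_rate
    n_removed = int((~keep).sum())
    if not keep.any():
        raise ValueError(
            "call-rate filter removed every marker; review the threshold "
            f"(min_call_rate={min_call_rate})")
    idx = np.flatnonzero(keep)
    return GenotypePanel(panel.markers.take(idx), list(panel.sample_ids),
                         panel.G[:, idx], panel.groups), n_removed


def allele_frequencies(panel: GenotypePanel, by_group: bool = False):
    """Coded-allele frequency per marker from non-missing calls only.

    With ``by_group`` returns ``{group: AlleleFrequencies}`` computed within
    each group label.
    """
    if by_group:
        if panel.groups is None:
            raise ValueError("panel has no group labels")
        out = {}
        for grp in dict.fromkeys(panel.groups):
            rows = [i for i, g in enumerate(panel.groups) if g == grp]
            sub = GenotypePanel(panel.markers, [panel.sample_ids[i] for i in rows],
                                panel.G[rows], None)
            out[grp] = allele_frequencies(sub)
        return out
    called = panel.G != MISSING
    n_obs = called.sum(axis=0)
    if np.any(n_obs == 0):
        j = int(np.argmin(n_obs))
        raise ValueError(
            f"marker {panel.markers.marker_id[j]!r} has zero non-missing calls; "
            "apply filter_call_rate first")
    dosage_sum = np.where(called, panel.G, 0).sum(axis=0)
    return AlleleFrequencies(dosage_sum / (2.0 * n_obs), n_obs)


def assign_gpos(mmap: MarkerMap, cm_per_mb: float = 1.0) -> MarkerMap:
    """Place markers on the Morgan scale.

    An explicit genetic-distance column (any positive gpos already present)
    takes precedence; otherwise positions are converted from bp at a constant
    ``cm_per_mb`` rate: gpos = bp * cm_per_mb / 1e8 Morgans.
    """
    if cm_per_mb < 0:
        raise ValueError("cm_per_mb must be non-negative")
    if np.any(mmap.gpos > 0):
        return mmap
    return replace(mmap, gpos=mmap.bp * cm_per_mb / 1e8)
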