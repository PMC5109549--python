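"""Genotype and phenotype containers plus readers/writers.

Genotypes are held as an individuals x markers matrix of additive allele
dosages: 0/1/2 for outbred diploids, {0, 2} for fully inbred material so
that the dosage scale is shared between the two modes.  Markers carry
chromosome and 1-based base-pair coordinates and are kept sorted by
genome position.  Missing calls are NaN until :func:`impute_missing`
replaces them by the per-marker observed mean.

Perfectly correlated markers carry no independent statistical
information; :func:`deduplicate_markers` collapses each class of
markers with |Pearson r| = 1 (up to a tolerance) onto its first member
in genome order and records the collapsed markers in a
:class:`DuplicateMap` so they can be reinstated into result clusters
for localization.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])  # bed magic, SNP-major


def _natural_chrom_key(label: str):
    """Sort key putting chr2 before chr10 and numeric labels in order."""
    parts = re.split(r"(\d+)", str(label))
    return tuple(int(p) if p.isdigit() else p for p in parts)


@dataclass
class GenotypeMatrix:
    """Additive-coded marker matrix with genome coordinates.

    Parameters
    ----------
    values : (n_individuals, p_markers) float array
        Allele dosages; NaN marks missing calls.  After mean imputation
        entries may be fractional.
    individual_ids, marker_ids : lists of str
    chrom : (p,) array of chromosome labels
    pos_bp : (p,) int array, 1-based positions
    ploidy_mode : {"outbred", "inbred"}
    """

    values: np.ndarray
    individual_ids: list
    marker_ids: list
    chrom: np.ndarray
    pos_bp: np.ndarray
    ploidy_mode: str = "outbred"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (individuals x markers)")
        n, p = self.values.shape
        if n < 2 or p < 1:
            raise ValueError(f"need n >= 2 individuals and p >= 1 markers, got {n} x {p}")
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        if not (len(self.individual_ids) == n and len(self.marker_ids) == p
                and len(self.chrom) == p and len(self.pos_bp) == p):
            raise ValueError("metadata lengths do not match matrix shape")
        if len(set(self.marker_ids)) != p:
            raise ValueError("duplicate marker IDs")
        if self.ploidy_mode not in ("outbred", "inbred"):
            raise ValueError(f"unknown ploidy_mode {self.ploidy_mode!r}")
        self._sort_by_position()

    # -- basic views ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def p_markers(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def marker_variances(self) -> np.ndarray:
        return np.nanvar(self.values, axis=0)

    def _sort_by_position(self):
        order = sorted(
            range(self.p_markers),
            key=lambda j: (_natural_chrom_key(self.chrom[j]), self.pos_bp[j]),
        )
        if order != list(range(self.p_markers)):
            logger.warning("markers were not in genome order; sorting")
            self._take_markers(np.asarray(order))
        # positions strictly increasing within chromosome
        same = (self.chrom[1:] == self.chrom[:-1]) & (np.diff(self.pos_bp) <= 0)
        if same.any():
            j = int(np.flatnonzero(same)[0]) + 1
            raise ValueError(
                f"duplicate/non-increasing position at marker {self.marker_ids[j]} "
                f"({self.chrom[j]}:{self.pos_bp[j]})"
            )

    def _take_markers(self, idx: np.ndarray):
        self.values = self.values[:, idx]
        self.marker_ids = [self.marker_ids[j] for j in idx]
        self.chrom = self.chrom[idx]
        self.pos_bp = self.pos_bp[idx]

    def subset_markers(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            self.values[:, idx],
            list(self.individual_ids),
            [self.marker_ids[j] for j in idx],
            self.chrom[idx],
            self.pos_bp[idx],
            self.ploidy_mode,
        )

    def subset_individuals(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            self.values[idx],
            [self.individual_ids[i] for i in idx],
            list(self.marker_ids),
            self.chrom.copy(),
            self.pos_bp.copy(),
            self.ploidy_mode,
        )

    def marker_positions(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker_id": self.marker_ids, "chrom": self.chrom, "pos_bp": self.pos_bp}
        )


@dataclass
class DuplicateMap:
    """Representative marker -> collapsed perfectly-correlated markers.

    ``members[rep_id]`` is a list of ``(marker_id, sign)`` pairs; sign is
    -1 for markers anti-correlated with the representative (swapped
    allele coding), +1 otherwise.  ``dropped_zero_variance`` lists
    monomorphic markers removed from the analysis entirely.
    """

    members: dict = field(default_factory=dict)
    dropped_zero_variance: list = field(default_factory=list)

    def expanded_ids(self, rep_id: str) -> list:
        """All marker IDs represented by ``rep_id`` (itself first)."""
        return [rep_id] + [m for m, _ in self.members.get(rep_id, [])]

    def n_collapsed(self) -> int:
        return sum(len(v) for v in self.members.values())


@dataclass
class Phenotype:
    """Phenotype vector with optional fixed covariates.

    family "gaussian" for continuous traits, "binomial" for 0/1
    case-control status.
    """

    values: np.ndarray
    family: str = "gaussian"
    covariates: np.ndarray | None = None
    individual_ids: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "binomial":
            uniq = set(np.unique(self.values[~np.isnan(self.values)]))
            if not uniq <= {0.0, 1.0}:
                raise ValueError("binomial phenotype must be coded 0/1")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != self.values.shape[0]:
                self.covariates = self.covariates.T
            if self.covariates.shape[0] != self.values.shape[0]:
                raise ValueError("covariate rows do not match phenotype length")
        if self.individual_ids is not None:
            self.individual_ids = [str(i) for i in self.individual_ids]
            if len(self.individual_ids) != len(self.values):
                raise ValueError("individual_ids length mismatch")


# ---------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------

def load_genotypes(path, format: str, ploidy_mode: str = "outbred") -> GenotypeMatrix:
    """Read genotypes from ``vcf``, ``plink`` (bed/bim/fam prefix) or a
    delimited ``table`` (rows = markers; first three columns marker_id,
    chrom, pos; remaining columns one per individual).

    VCF records are restricted to biallelic sites; dosages count the
    minor allele (ties broken toward ALT).  Missing calls become NaN.
    """
    path = str(path)
    if format == "table":
        return _read_table(path, ploidy_mode)
    if format == "vcf":
        return _read_vcf(path, ploidy_mode)
    if format == "plink":
        return _read_plink(path, ploidy_mode)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(G: GenotypeMatrix, path, format: str = "table") -> None:
    """Write genotypes as a delimited table or a PLINK1 bed/bim/fam triplet."""
    path = str(path)
    if format == "table":
        df = pd.DataFrame(G.values.T, columns=G.individual_ids)
        df.insert(0, "pos", G.pos_bp)
        df.insert(0, "chrom", G.chrom)
        df.insert(0, "marker_id", G.marker_ids)
        df.to_csv(path, sep="\t", index=False, na_rep="NA")
    elif format == "plink":
        _write_plink(G, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _read_table(path: str, ploidy_mode: str) -> GenotypeMatrix:
    sep = "\t"
    with open(path) as fh:
        header = fh.readline()
    if "\t" not in header and "," in header:
        sep = ","
    df = pd.read_csv(path, sep=sep, na_values=["NA", "NaN", ""])
    marker_ids = df.iloc[:, 0].astype(str).tolist()
    chrom = df.iloc[:, 1].to_numpy()
    pos = df.iloc[:, 2].to_numpy()
    values = df.iloc[:, 3:].to_numpy(dtype=float).T
    return GenotypeMatrix(values, list(df.columns[3:]), marker_ids, chrom, pos, ploidy_mode)


def _read_vcf(path: str, ploidy_mode: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    individual_ids = list(vcf.samples)
    cols, ids, chroms, poss = [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = np.asarray(var.gt_types, dtype=float)
        dos = np.full_like(gt, np.nan)
        dos[gt == 0] = 0.0
        dos[gt == 1] = 1.0
        dos[gt == 3] = 2.0
        # count the minor allele; ties broken toward ALT
        obs = dos[~np.isnan(dos)]
        if obs.size and obs.mean() > 1.0:
            dos = 2.0 - dos
        cols.append(dos)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
    vcf.close()
    if n_skipped:
        logger.info("skipped %d non-biallelic VCF records", n_skipped)
    if not cols:
        raise ValueError(f"no biallelic records in {path}")
    return GenotypeMatrix(np.column_stack(cols), individual_ids, ids, np.asarray(chroms, dtype=object), np.asarray(poss), ploidy_mode)


def _plink_prefix(path: str) -> str:
    return path[:-4] if path.endswith((".bed", ".bim", ".fam")) else path


def _read_plink(path: str, ploidy_mode: str) -> GenotypeMatrix:
    prefix = _plink_prefix(path)
    bim = pd.read_csv(
        prefix + ".bim", sep=r"\s+", header=None,
        names=["chrom", "marker_id", "cm", "pos", "a1", "a2"],
    )
    fam = pd.read_csv(
        prefix + ".fam", sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "phen"],
    )
    n, p = len(fam), len(bim)
    with open(prefix + ".bed", "rb") as fh:
        raw = fh.read()
    if raw[:3] != _PLINK_MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK1 bed file")
    nbytes = (n + 3) // 4
    data = np.frombuffer(raw[3:], dtype=np.uint8).reshape(p, nbytes)
    # unpack 2-bit codes, little-endian within byte
    codes = np.empty((p, nbytes * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (data >> (2 * k)) & 0b11
    codes = codes[:, :n]
    # 00 -> 2 copies of A1, 10 -> 1, 11 -> 0, 01 -> missing
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    values = lut[codes].T
    return GenotypeMatrix(
        values, fam["iid"].astype(str).tolist(), bim["marker_id"].astype(str).tolist(),
        bim["chrom"].to_numpy(), bim["pos"].to_numpy(), ploidy_mode,
    )


def _write_plink(G: GenotypeMatrix, path: str) -> None:
    prefix = _plink_prefix(path)
    vals = G.values
    ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
    if not ok.all():
        raise ValueError("PLINK writer requires integer dosages 0/1/2 (or missing)")
    bim = pd.DataFrame({
        "chrom": G.chrom, "marker_id": G.marker_ids, "cm": 0,
        "pos": G.pos_bp, "a1": "A", "a2": "B",
    })
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame({
        "fid": G.individual_ids, "iid": G.individual_ids,
        "pat": 0, "mat": 0, "sex": 0, "phen": -9,
    })
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)
    n, p = vals.shape
    codes = np.full((p, n), 1, dtype=np.uint8)  # 01 = missing
    codes[vals.T == 2.0] = 0b00
    codes[vals.T == 1.0] = 0b10
    codes[vals.T == 0.0] = 0b11
    nbytes = (n + 3) // 4
    padded = np.ones((p, nbytes * 4), dtype=np.uint8) * 0  # pad with 00; ignored on read
    padded[:, :n] = codes
    packed = np.zeros((p, nbytes), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_PLINK_MAGIC)
        fh.write(packed.tobytes())


def load_phenotype(path, family: str = "gaussian", value_col: str | None = None,
                   covariate_cols: list | None = None) -> Phenotype:
    """Read a delimited phenotype table keyed by individual ID.

    The first column is the individual ID; ``value_col`` (default:
    second column) holds the trait; ``covariate_cols`` name optional
    fixed covariates.
    """
    with open(str(path)) as fh:
        header = fh.readline()
    sep = "," if ("\t" not in header and "," in header) else "\t"
    df = pd.read_csv(path, sep=sep)
    ids = df.iloc[:, 0].astype(str).tolist()
    if value_col is None:
        value_col = df.columns[1]
    cov = df[covariate_cols].to_numpy(dtype=float) if covariate_cols else None
    return Phenotype(df[value_col].to_numpy(dtype=float), family, cov, ids)


def write_phenotype(ph: Phenotype, path, value_col: str = "value") -> None:
    ids = ph.individual_ids or [str(i) for i in range(len(ph.values))]
    df = pd.DataFrame({"individual_id": ids, value_col: ph.values})
    if ph.covariates is not None:
        for q in range(ph.covariates.shape[1]):
            df[f"covariate_{q + 1}"] = ph.covariates[:, q]
    df.to_csv(str(path), sep="\t", index=False)


def align(G: GenotypeMatrix, ph: Phenotype) -> tuple[GenotypeMatrix, Phenotype]:
    """Intersect genotype and phenotype on individual IDs (genotype order)."""
    if ph.individual_ids is None:
        if len(ph.values) != G.n_individuals:
            raise ValueError("phenotype has no IDs and length differs from genotypes")
        return G, ph
    pos = {iid: i for i, iid in enumerate(ph.individual_ids)}
    keep = [i for i, iid in enumerate(G.individual_ids) if iid in pos]
    if len(keep) < 2:
        raise ValueError("fewer than 2 individuals shared between genotypes and phenotype")
    sel = [pos[G.individual_ids[i]] for i in keep]
    Gs = G.subset_individuals(keep) if len(keep) != G.n_individuals else G
    ph2 = Phenotype(
        ph.values[sel], ph.family,
        ph.covariates[sel] if ph.covariates is not None else None,
        [ph.individual_ids[i] for i in sel],
    )
    return Gs, ph2


# ---------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------

def impute_missing(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls by the per-marker observed mean dosage."""
    if not G.has_missing:
        return G
    vals = G.values.copy()
    n_obs = (~np.isnan(vals)).sum(axis=0)
    if (n_obs == 0).any():
        j = int(np.flatnonzero(n_obs == 0)[0])
        raise ValueError(f"marker {G.marker_ids[j]} has no observed genotypes")
    means = np.nanmean(vals, axis=0)
    idx = np.where(np.isnan(vals))
    vals[idx] = means[idx[1]]
    return GenotypeMatrix(vals, list(G.individual_ids), list(G.marker_ids),
                          G.chrom.copy(), G.pos_bp.copy(), G.ploidy_mode)


def deduplicate_markers(G: GenotypeMatrix, tol: float = 1e-12) -> tuple[GenotypeMatrix, DuplicateMap]:
    """Collapse classes of perfectly correlated markers.

    Markers with |Pearson r| >= 1 - tol are represented by their first
    member in genome order; anti-correlated members get sign -1 in the
    returned :class:`DuplicateMap`.  Zero-variance (monomorphic) markers
    are dropped and logged.  Candidate classes are found by hashing the
    sign-canonicalized standardized columns, then verified exactly, so
    the common case avoids all-pairs correlation.
    """
    if G.has_missing:
        raise ValueError("impute missing genotypes before deduplication")
    vals = G.values
    n, p = vals.shape
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0)
    poly = sd > 0
    dropped = [G.marker_ids[j] for j in np.flatnonzero(~poly)]
    if dropped:
        logger.info("dropped %d zero-variance markers", len(dropped))
    dup = DuplicateMap(dropped_zero_variance=dropped)

    Z = np.zeros_like(vals)
    Z[:, poly] = (vals[:, poly] - mean[poly]) / sd[poly]
    keep: list[int] = []
    buckets: dict[bytes, list[int]] = {}
    for j in np.flatnonzero(poly):
        z = Z[:, j]
        nz = z[np.abs(z) > 0]
        sign = 1.0 if (nz.size == 0 or nz[0] > 0) else -1.0
        key = np.round(sign * z, 8).tobytes()
        buckets.setdefault(key, []).append(j)

    # exact verification within each hash bucket against its representative
    rep_of: dict[int, tuple[int, int]] = {}   # member -> (rep, sign)
    for bucket in buckets.values():
        reps_in_bucket: list[int] = []
        for j in bucket:
            placed = False
            for r in reps_in_bucket:
                r_jr = float(Z[:, j] @ Z[:, r]) / n
                if abs(r_jr) >= 1.0 - tol:
                    rep_of[j] = (r, 1 if r_jr > 0 else -1)
                    placed = True
                    break
            if not placed:
                reps_in_bucket.append(j)
        keep.extend(reps_in_bucket)

    keep.sort()
    for j, (r, s) in sorted(rep_of.items()):
        dup.members.setdefault(G.marker_ids[r], []).append((G.marker_ids[j], s))
    G2 = G.subset_markers(np.asarray(keep, dtype=int))
    return G2, dup
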