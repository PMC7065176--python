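"""Readers, writers and cross-table validation for genotype, locality and
environment data.

Supported dialects:

* VCF 4.2, biallelic SNPs, ``GT`` field only (read via :mod:`cyvcf2`, written
  as plain text with unphased separators).
* Locality CSV with columns ``sample, locality, lat, lon``.
* Long-format environment CSV with columns ``locality, variable, category, value``.

Dosages are diploid alternate-allele counts in ``{0, 1, 2}``; missing calls
(including half-calls such as ``./1``) are ``NaN``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "Bundle",
    "JoinError",
    "read_vcf",
    "write_vcf",
    "read_locality",
    "write_locality",
    "read_env",
    "write_env",
    "env_wide",
    "validate_join",
]

MISSING = np.nan


class JoinError(ValueError):
    """Raised when genotype, locality and environment tables do not cross-reference.

    Carries *all* violations found, one per line, so callers can fix them in a
    single pass.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "validation failed with %d violation(s):\n%s"
            % (len(self.violations), "\n".join("  - " + v for v in self.violations))
        )


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix for samples x biallelic loci.

    Parameters
    ----------
    samples
        Unique sample identifiers, one per matrix row.
    loci
        DataFrame with columns ``chrom, pos, ref, alt``; ``pos`` is 1-based as
        in VCF. Rows are sorted by (chrom, pos) on construction.
    dosages
        Float array of shape ``(n_samples, n_loci)`` with values in
        ``{0, 1, 2, NaN}``.
    """

    samples: list[str]
    loci: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids in GenotypeMatrix")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")
        self.loci = self.loci.reset_index(drop=True)
        order = self.loci.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
        if not np.array_equal(order, np.arange(len(self.loci))):
            self.loci = self.loci.iloc[order].reset_index(drop=True)
            self.dosages = self.dosages[:, order]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def positions(self) -> np.ndarray:
        return self.loci["pos"].to_numpy()

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per locus over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def subset_samples(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in keep]
        return GenotypeMatrix(list(keep), self.loci.copy(), self.dosages[idx])

    def subset_loci(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            list(self.samples), self.loci.loc[mask].reset_index(drop=True),
            self.dosages[:, mask],
        )

    def filter_loci(self, min_maf: float = 0.0, max_missing: float = 1.0) -> "GenotypeMatrix":
        """Drop loci below the minor-allele-frequency floor or above the
        missingness ceiling. Loci with no data at all are always dropped."""
        p = self.allele_freq()
        maf = np.fmin(p, 1.0 - p)
        miss = self.missing_rate()
        keep = ~np.isnan(p) & (maf >= min_maf) & (miss <= max_missing)
        return self.subset_loci(keep)


def _gt_to_dosage(a1: int, a2: int) -> float:
    # half-calls (one allele missing) are treated as fully missing
    if a1 < 0 or a2 < 0:
        return MISSING
    return float(a1 + a2)


def read_vcf(path: str | os.PathLike, min_maf: float = 0.0,
             max_missing: float = 1.0) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records and non-SNP records (indels, MNPs, symbolic alleles)
    are skipped. The GT field is parsed to a dosage regardless of the phasing
    separator. Loci failing the MAF or missingness filters are dropped.

    Raises
    ------
    ValueError
        If a record lacks a GT field, or no locus survives filtering.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    rows: list[tuple] = []
    dosage_rows: list[np.ndarray] = []
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue
        if v.ALT[0] not in "ACGT" or v.REF not in "ACGT":
            continue
        if "GT" not in v.FORMAT:
            raise ValueError(
                f"record {v.CHROM}:{v.POS} has no GT field; only GT genotypes are supported"
            )
        gts = v.genotypes
        dos = np.array([_gt_to_dosage(g[0], g[1]) for g in gts], dtype=float)
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        dosage_rows.append(dos)
    vcf.close()
    if not rows:
        raise ValueError(f"no biallelic SNP records found in {path}")
    loci = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    gm = GenotypeMatrix(samples, loci, np.column_stack(dosage_rows))
    gm = gm.filter_loci(min_maf=min_maf, max_missing=max_missing)
    if gm.n_loci == 0:
        raise ValueError(
            f"no loci pass filters (min_maf={min_maf}, max_missing={max_missing})"
        )
    return gm


_DOSAGE_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a :class:`GenotypeMatrix` as VCF 4.2 text.

    Genotypes use the unphased ``/`` separator; missing dosages become
    ``./.``. One ``##contig`` header line is emitted per chromosome, with
    length taken as the largest position observed.
    """
    if gm.n_loci == 0:
        raise ValueError("refusing to write an empty genotype matrix")
    lines = ["##fileformat=VCFv4.2"]
    for chrom, sub in gm.loci.groupby("chrom", sort=True):
        lines.append(f"##contig=<ID={chrom},length={int(sub['pos'].max())}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples))
    for j, locus in gm.loci.iterrows():
        gts = "\t".join(
            _DOSAGE_GT.get(gm.dosages[i, j], "./.") for i in range(gm.n_samples)
        )
        lines.append(
            f"{locus.chrom}\t{int(locus.pos)}\t.\t{locus.ref}\t{locus.alt}"
            f"\t.\tPASS\t.\tGT\t{gts}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


LOCALITY_COLUMNS = ["sample", "locality", "lat", "lon"]
ENV_COLUMNS = ["locality", "variable", "category", "value"]


def read_locality(path: str | os.PathLike) -> pd.DataFrame:
    loc = pd.read_csv(path)
    missing = set(LOCALITY_COLUMNS) - set(loc.columns)
    if missing:
        raise ValueError(f"locality table missing columns: {sorted(missing)}")
    if loc["sample"].duplicated().any():
        dups = loc.loc[loc["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample rows in locality table: {dups}")
    if (loc["lat"].abs() > 90).any() or (loc["lon"].abs() > 180).any():
        raise ValueError("coordinates out of range (|lat|<=90, |lon|<=180)")
    return loc[LOCALITY_COLUMNS].copy()


def write_locality(loc: pd.DataFrame, path: str | os.PathLike) -> None:
    loc[LOCALITY_COLUMNS].to_csv(path, index=False)


def read_env(path: str | os.PathLike) -> pd.DataFrame:
    env = pd.read_csv(path)
    missing = set(ENV_COLUMNS) - set(env.columns)
    if missing:
        raise ValueError(f"environment table missing columns: {sorted(missing)}")
    return env[ENV_COLUMNS].copy()


def write_env(env: pd.DataFrame, path: str | os.PathLike) -> None:
    env[ENV_COLUMNS].to_csv(path, index=False)


def env_wide(env: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long environment table to locality x variable."""
    return env.pivot(index="locality", columns="variable", values="value")


@dataclass
class Bundle:
    """A genotype matrix plus locality and environment tables whose
    cross-references have been validated by :func:`validate_join`."""

    genotypes: GenotypeMatrix
    localities: pd.DataFrame
    environment: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=ENV_COLUMNS))

    def locality_of(self) -> dict[str, str]:
        return dict(zip(self.localities["sample"], self.localities["locality"]))

    def locality_coords(self) -> pd.DataFrame:
        return (
            self.localities.groupby("locality")[["lat", "lon"]].first()
        )


def validate_join(gm: GenotypeMatrix, loc: pd.DataFrame,
                  env: pd.DataFrame | None = None) -> Bundle:
    """Check that every sample maps to a locality and every locality has a full
    environment grid. All violations are collected before raising."""
    violations: list[str] = []
    loc_samples = set(loc["sample"])
    for s in gm.samples:
        if s not in loc_samples:
            violations.append(f"sample {s!r} has no locality row")
    dup = loc.loc[loc["sample"].duplicated(), "sample"].tolist()
    for s in dup:
        violations.append(f"sample {s!r} appears more than once in locality table")
    if env is None:
        env = pd.DataFrame(columns=ENV_COLUMNS)
    if len(env):
        variables = sorted(env["variable"].unique())
        have = {(r.locality, r.variable) for r in env.itertuples()}
        for locality in sorted(loc["locality"].unique()):
            for var in variables:
                if (locality, var) not in have:
                    violations.append(
                        f"locality {locality!r} missing environment value for {var!r}"
                    )
        if env["value"].isna().any():
            bad = env.loc[env["value"].isna(), ["locality", "variable"]]
            for r in bad.itertuples():
                violations.append(
                    f"locality {r.locality!r} has NA environment value for {r.variable!r}"
                )
    if violations:
        raise JoinError(violations)
    return Bundle(gm, loc.reset_index(drop=True), env.reset_index(drop=True))
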