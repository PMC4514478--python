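"""PLINK text-format genotype I/O and the in-memory genotype container.

The package's single genotype container is :class:`GenotypeMatrix`: a dense
samples x variants array of counted-allele copies (0/1/2, ``-1`` for missing)
plus pandas tables of sample and variant metadata.  All other modules consume
and return this container.

Supported interchange formats are the PLINK text formats: sample-major
PED/MAP and variant-major TPED/TFAM.  Binary BED is deliberately not parsed
here; text formats keep every fixture human-readable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING: int = -1

#: phenotype codes used internally (PLINK uses 1=control, 2=case on disk)
CONTROL, CASE, PHENO_MISSING = 0, 1, -9

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "0": "0"}

VARIANT_COLUMNS = ["chrom", "pos", "snp_id", "allele1", "allele2", "counted_allele"]
SAMPLE_COLUMNS = ["sample_id", "phenotype", "sex"]


class GenotypeParseError(ValueError):
    """Raised when a PLINK text file fails to parse; names the offending line."""


@dataclass
class GenotypeMatrix:
    """Case/control genotypes: calls count copies of each variant's counted allele.

    Attributes
    ----------
    samples : pandas.DataFrame
        One row per individual with columns ``sample_id`` (unique string),
        ``phenotype`` (0=control, 1=case, -9=missing) and ``sex``
        (1=male, 2=female, 0=unknown).
    variants : pandas.DataFrame
        One row per variant with columns ``chrom``, ``pos`` (1-based bp),
        ``snp_id`` (unique), ``allele1``, ``allele2`` and ``counted_allele``
        (the base whose copies the calls count).
    calls : numpy.ndarray
        ``(n_samples, n_variants)`` int8 array with values in {0, 1, 2} or
        ``-1`` for a missing genotype.
    """

    samples: pd.DataFrame
    variants: pd.DataFrame
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be in {0, 1, 2} or -1 (missing)")
        if self.samples["sample_id"].duplicated().any():
            dups = self.samples["sample_id"][self.samples["sample_id"].duplicated()]
            raise ValueError(f"duplicate sample ids: {list(dups[:5])}")
        if self.variants["snp_id"].duplicated().any():
            dups = self.variants["snp_id"][self.variants["snp_id"].duplicated()]
            raise ValueError(f"duplicate SNP ids: {list(dups[:5])}")
        self.samples = self.samples.reset_index(drop=True)
        self.variants = self.variants.reset_index(drop=True)

    # ---- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def is_case(self) -> np.ndarray:
        return (self.samples["phenotype"].to_numpy() == CASE)

    @property
    def is_control(self) -> np.ndarray:
        return (self.samples["phenotype"].to_numpy() == CONTROL)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    # ---- subsetting ----------------------------------------------------------
    def take_samples(self, index) -> "GenotypeMatrix":
        """Return a copy restricted to the given sample positions (order kept)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=self.samples.iloc[index].reset_index(drop=True),
            variants=self.variants.copy(),
            calls=self.calls[index, :].copy(),
        )

    def take_variants(self, index) -> "GenotypeMatrix":
        """Return a copy restricted to the given variant positions (order kept)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=self.samples.copy(),
            variants=self.variants.iloc[index].reset_index(drop=True),
            calls=self.calls[:, index].copy(),
        )

    def flip_counted_allele(self, variant_index) -> "GenotypeMatrix":
        """Re-orient the counted allele at the given variants: calls map g -> 2-g."""
        out = GenotypeMatrix(self.samples.copy(), self.variants.copy(), self.calls.copy())
        idx = np.atleast_1d(np.asarray(variant_index))
        for j in idx:
            a1 = out.variants.at[j, "allele1"]
            a2 = out.variants.at[j, "allele2"]
            cur = out.variants.at[j, "counted_allele"]
            out.variants.at[j, "counted_allele"] = a2 if cur == a1 else a1
        sub = out.calls[:, idx]
        nonmiss = sub != MISSING
        sub[nonmiss] = 2 - sub[nonmiss]
        out.calls[:, idx] = sub
        return out

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples.reset_index(drop=True).equals(other.samples.reset_index(drop=True))
            and self.variants.reset_index(drop=True).equals(other.variants.reset_index(drop=True))
            and np.array_equal(self.calls, other.calls)
        )


# ---- PED/MAP ----------------------------------------------------------------

def _parse_pheno(code: str) -> int:
    if code == "1":
        return CONTROL
    if code == "2":
        return CASE
    return PHENO_MISSING  # 0, -9 and anything unphenotyped


def _format_pheno(code: int) -> str:
    return {CONTROL: "1", CASE: "2"}.get(int(code), "-9")


def read_map(map_path) -> pd.DataFrame:
    """Parse a PLINK MAP file (chrom, snp_id, [cM,] bp) into a variant table."""
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 4:
                chrom, snp_id, _cm, pos = parts
            elif len(parts) == 3:
                chrom, snp_id, pos = parts
            else:
                raise GenotypeParseError(f"{map_path}:{lineno}: expected 3 or 4 fields, got {len(parts)}")
            rows.append((chrom, int(pos), snp_id))
    var = pd.DataFrame(rows, columns=["chrom", "pos", "snp_id"])
    if var["snp_id"].duplicated().any():
        dup = var["snp_id"][var["snp_id"].duplicated()].iloc[0]
        raise GenotypeParseError(f"{map_path}: duplicate SNP id {dup!r}")
    return var


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Read a sample-major PED plus its MAP into a :class:`GenotypeMatrix`.

    Genotype ``0 0`` becomes missing; phenotype 1/2 map to control/case and
    0/-9 to missing.  The counted allele of each variant is initialised to the
    first allele observed for it (``allele1``); monomorphic variants get the
    placeholder second allele ``"0"``.
    """
    variants = read_map(map_path)
    m = len(variants)
    sample_rows = []
    geno_rows = []
    # allele registry per variant, in order of first observation
    alleles: list[list[str]] = [[] for _ in range(m)]
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise GenotypeParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields for {m} variants, got {len(parts)}"
                )
            _fid, iid, _pat, _mat, sex, pheno = parts[:6]
            sample_rows.append((iid, _parse_pheno(pheno), int(sex) if sex in ("1", "2") else 0))
            gt = parts[6:]
            row = np.empty(m, dtype=np.int8)
            for j in range(m):
                a, b = gt[2 * j], gt[2 * j + 1]
                if a == "0" or b == "0":
                    if a != b:
                        raise GenotypeParseError(
                            f"{ped_path}:{lineno}: half-missing genotype {a} {b} at variant {j + 1}"
                        )
                    row[j] = MISSING
                    continue
                reg = alleles[j]
                for al in (a, b):
                    if al not in reg:
                        reg.append(al)
                        if len(reg) > 2:
                            raise GenotypeParseError(
                                f"{ped_path}:{lineno}: variant {variants['snp_id'].iloc[j]!r} "
                                f"has >2 alleles: {reg}"
                            )
                row[j] = (a == reg[0]) + (b == reg[0])  # copies of allele1
            geno_rows.append(row)
    samples = pd.DataFrame(sample_rows, columns=SAMPLE_COLUMNS)
    variants = variants.copy()
    variants["allele1"] = [reg[0] if reg else "0" for reg in alleles]
    variants["allele2"] = [reg[1] if len(reg) > 1 else "0" for reg in alleles]
    variants["counted_allele"] = variants["allele1"]
    calls = (
        np.vstack(geno_rows)
        if geno_rows
        else np.empty((0, m), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls)


def write_map(variants: pd.DataFrame, map_path) -> None:
    with open(map_path, "w") as fh:
        for row in variants.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.pos}\n")


def write_ped_map(matrix: GenotypeMatrix, out_prefix) -> None:
    """Write ``<prefix>.ped`` and ``<prefix>.map``; re-readable to an equal matrix."""
    write_map(matrix.variants, f"{out_prefix}.map")
    counted = matrix.variants["counted_allele"].to_numpy()
    a1 = matrix.variants["allele1"].to_numpy()
    a2 = matrix.variants["allele2"].to_numpy()
    other = np.where(counted == a1, a2, a1)
    with open(f"{out_prefix}.ped", "w") as fh:
        for i, srow in enumerate(matrix.samples.itertuples(index=False)):
            fields = [srow.sample_id, srow.sample_id, "0", "0",
                      str(int(srow.sex)), _format_pheno(srow.phenotype)]
            row = matrix.calls[i]
            for j in range(matrix.n_variants):
                g = row[j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 2:
                    fields += [counted[j], counted[j]]
                elif g == 1:
                    fields += [counted[j], other[j]]
                else:
                    fields += [other[j], other[j]]
            fh.write(" ".join(fields) + "\n")


# ---- TPED/TFAM --------------------------------------------------------------

def read_tped_tfam(tped_path, tfam_path) -> GenotypeMatrix:
    """Read variant-major TPED plus TFAM into a :class:`GenotypeMatrix`."""
    sample_rows = []
    with open(tfam_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6:
                raise GenotypeParseError(f"{tfam_path}:{lineno}: expected 6 fields, got {len(parts)}")
            _fid, iid, _pat, _mat, sex, pheno = parts
            sample_rows.append((iid, _parse_pheno(pheno), int(sex) if sex in ("1", "2") else 0))
    samples = pd.DataFrame(sample_rows, columns=SAMPLE_COLUMNS)
    n = len(samples)

    var_rows = []
    geno_cols = []
    with open(tped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4 + 2 * n:
                raise GenotypeParseError(
                    f"{tped_path}:{lineno}: expected {4 + 2 * n} fields for {n} samples, got {len(parts)}"
                )
            chrom, snp_id, _cm, pos = parts[:4]
            gt = parts[4:]
            reg: list[str] = []
            col = np.empty(n, dtype=np.int8)
            for i in range(n):
                a, b = gt[2 * i], gt[2 * i + 1]
                if a == "0" or b == "0":
                    if a != b:
                        raise GenotypeParseError(f"{tped_path}:{lineno}: half-missing genotype")
                    col[i] = MISSING
                    continue
                for al in (a, b):
                    if al not in reg:
                        reg.append(al)
                        if len(reg) > 2:
                            raise GenotypeParseError(
                                f"{tped_path}:{lineno}: variant {snp_id!r} has >2 alleles: {reg}"
                            )
                col[i] = (a == reg[0]) + (b == reg[0])
            var_rows.append((chrom, int(pos), snp_id,
                             reg[0] if reg else "0", reg[1] if len(reg) > 1 else "0"))
            geno_cols.append(col)
    variants = pd.DataFrame(var_rows, columns=["chrom", "pos", "snp_id", "allele1", "allele2"])
    if variants["snp_id"].duplicated().any():
        dup = variants["snp_id"][variants["snp_id"].duplicated()].iloc[0]
        raise GenotypeParseError(f"{tped_path}: duplicate SNP id {dup!r}")
    variants["counted_allele"] = variants["allele1"]
    calls = np.column_stack(geno_cols) if geno_cols else np.empty((n, 0), dtype=np.int8)
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls)


def write_tped_tfam(matrix: GenotypeMatrix, out_prefix) -> None:
    with open(f"{out_prefix}.tfam", "w") as fh:
        for srow in matrix.samples.itertuples(index=False):
            fh.write(f"{srow.sample_id} {srow.sample_id} 0 0 "
                     f"{int(srow.sex)} {_format_pheno(srow.phenotype)}\n")
    counted = matrix.variants["counted_allele"].to_numpy()
    a1 = matrix.variants["allele1"].to_numpy()
    a2 = matrix.variants["allele2"].to_numpy()
    other = np.where(counted == a1, a2, a1)
    with open(f"{out_prefix}.tped", "w") as fh:
        for j, vrow in enumerate(matrix.variants.itertuples(index=False)):
            fields = [str(vrow.chrom), vrow.snp_id, "0", str(vrow.pos)]
            col = matrix.calls[:, j]
            for g in col:
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 2:
                    fields += [counted[j], counted[j]]
                elif g == 1:
                    fields += [counted[j], other[j]]
                else:
                    fields += [other[j], other[j]]
            fh.write(" ".join(fields) + "\n")


def orient_like(matrix: GenotypeMatrix, reference_variants: pd.DataFrame) -> GenotypeMatrix:
    """Re-orient counted alleles to match a reference variant table.

    PED/TPED files store unordered allele pairs, so a freshly read matrix
    initialises each counted allele to the first base observed in the file;
    this helper flips variants whose orientation differs from the reference
    (matched by ``snp_id``), making write -> read -> orient_like the exact
    identity on genotype content.
    """
    ref = reference_variants.set_index("snp_id")
    out = GenotypeMatrix(matrix.samples.copy(), matrix.variants.copy(),
                         matrix.calls.copy())
    for j, row in enumerate(matrix.variants.itertuples(index=False)):
        if row.snp_id not in ref.index:
            continue
        rrow = ref.loc[row.snp_id]
        want = rrow["counted_allele"]
        if row.counted_allele == want:
            continue
        if want not in (row.allele1, row.allele2) and row.allele2 != "0":
            continue  # alleles genuinely disagree; leave untouched
        # flip orientation; a monomorphic placeholder adopts the reference's
        # allele labels (the file simply never showed the second allele)
        col = out.calls[:, j]
        nonmiss = col != MISSING
        col[nonmiss] = 2 - col[nonmiss]
        out.calls[:, j] = col
        out.variants.at[j, "counted_allele"] = want
        if row.allele2 == "0":
            out.variants.at[j, "allele1"] = rrow["allele1"]
            out.variants.at[j, "allele2"] = rrow["allele2"]
    return out


# ---- phenotype override ------------------------------------------------------

def apply_phenotype_table(matrix: GenotypeMatrix, path) -> GenotypeMatrix:
    """Override phenotypes from a two-column tab-separated file (sample_id, phenotype).

    Phenotype values use the PLINK disk convention: 1=control, 2=case,
    0/-9=missing.  Samples absent from the file keep their phenotype.
    """
    tab = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "phenotype"],
                      dtype={"sample_id": str, "phenotype": str})
    mapping = {r.sample_id: _parse_pheno(r.phenotype) for r in tab.itertuples(index=False)}
    samples = matrix.samples.copy()
    samples["phenotype"] = [
        mapping.get(sid, ph) for sid, ph in zip(samples["sample_id"], samples["phenotype"])
    ]
    return GenotypeMatrix(samples=samples, variants=matrix.variants.copy(),
                          calls=matrix.calls.copy())


# ---- panel intersection ------------------------------------------------------

def _is_ambiguous(a1: str, a2: str) -> bool:
    """A/T and C/G pairs cannot be strand-resolved from allele labels alone."""
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def intersect_panels(a: GenotypeMatrix, b: GenotypeMatrix):
    """Restrict two cohorts to their shared SNP ids with alleles harmonized.

    Shared SNPs are matched by ``snp_id``.  For each shared SNP, ``b``'s
    allele pair must equal ``a``'s either directly or after complementing
    both alleles (a strand flip); otherwise the SNP is dropped.
    Strand-ambiguous SNPs (A/T, C/G) are dropped, with a logged count, since
    a flip cannot be detected for them.  After matching, ``b``'s counted
    allele is re-oriented to agree with ``a``'s, so identical individuals
    would receive identical calls from either panel.

    Returns ``(a_sub, b_sub)`` with identical variant order.

    Raises
    ------
    ValueError
        If the panels share no usable SNPs.
    """
    ids_a = a.variants.set_index("snp_id")
    ids_b = b.variants.set_index("snp_id")
    shared = [s for s in ids_a.index if s in set(ids_b.index)]
    if not shared:
        raise ValueError("panels share no SNP ids")

    keep, flip_b, n_ambiguous, n_incompatible = [], [], 0, 0
    for sid in shared:
        ra, rb = ids_a.loc[sid], ids_b.loc[sid]
        pa = {ra["allele1"], ra["allele2"]} - {"0"}
        pb = {rb["allele1"], rb["allele2"]} - {"0"}
        if len(pa) == 2 and _is_ambiguous(*sorted(pa)):
            n_ambiguous += 1
            continue
        flipped = False
        if pb and not pb <= pa:
            pb_c = {_COMPLEMENT.get(x, "?") for x in pb}
            if pb_c <= pa:
                flipped = True
            else:
                n_incompatible += 1
                continue
        keep.append(sid)
        counted_b = _COMPLEMENT.get(rb["counted_allele"], rb["counted_allele"]) if flipped \
            else rb["counted_allele"]
        flip_b.append(counted_b != ra["counted_allele"] and counted_b != "0")
    if n_ambiguous:
        log.info("intersect_panels: dropped %d strand-ambiguous SNPs", n_ambiguous)
    if n_incompatible:
        log.warning("intersect_panels: dropped %d SNPs with incompatible alleles", n_incompatible)
    if not keep:
        raise ValueError("panels share no usable SNPs after allele reconciliation")

    pos_a = {s: i for i, s in enumerate(a.variants["snp_id"])}
    pos_b = {s: i for i, s in enumerate(b.variants["snp_id"])}
    a_sub = a.take_variants([pos_a[s] for s in keep])
    b_sub = b.take_variants([pos_b[s] for s in keep])
    # rewrite b's allele labels onto a's strand and orient its counted allele
    b_sub.variants[["allele1", "allele2", "counted_allele"]] = \
        a_sub.variants[["allele1", "allele2", "counted_allele"]].to_numpy()
    to_flip = [j for j, f in enumerate(flip_b) if f]
    if to_flip:
        sub = b_sub.calls[:, to_flip]
        nonmiss = sub != MISSING
        sub[nonmiss] = 2 - sub[nonmiss]
        b_sub.calls[:, to_flip] = sub
        # flip restored counted allele back to a's orientation already set above
    return a_sub, b_sub
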