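"""File formats: PLINK .bed/.bim/.fam, TSV fallbacks, summary statistics,
phenotypes, density rasters, and provenance headers.

The .bed codec implements the standard SNP-major 2-bit encoding (magic
bytes 0x6c 0x1b, mode 0x01): per variant, each byte packs four samples,
low bits first — 00 = two copies of allele1, 10 = heterozygote, 11 = zero
copies, 01 = missing.  Dosages everywhere in this package count allele1.

Every TSV written here starts with '#'-prefixed provenance comment lines
(package version, seed, config hash) which all readers skip.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .migration import DensityMap

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01
# dosage of allele1 -> 2-bit code
_ENCODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}
_DECODE = np.array([2.0, np.nan, 1.0, 0.0])

MISSING_TOKEN = "NA"


def provenance_lines(seed: int | None = None, config_hash: str | None = None) -> list[str]:
    from . import __version__

    parts = [f"# prscreen v{__version__}"]
    if seed is not None:
        parts.append(f"# seed={seed}")
    if config_hash is not None:
        parts.append(f"# config_hash={config_hash}")
    return parts


def config_hash(obj: dict) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def write_plink(prefix: str | Path, genotypes: np.ndarray,
                variant_meta: pd.DataFrame, sample_ids) -> None:
    """Write .bed/.bim/.fam; genotypes are allele1 dosages with NaN missing."""
    prefix = Path(prefix)
    G = np.asarray(genotypes, dtype=float)
    n, m = G.shape
    if len(variant_meta) != m or len(sample_ids) != n:
        raise ValueError("genotype dimensions do not match metadata")

    codes = np.full((m, n), _ENCODE[-1], dtype=np.uint8)
    for dos, code in _ENCODE.items():
        if dos >= 0:
            codes[(G.T == dos)] = code
    nbytes = (n + 3) // 4
    packed = np.zeros((m, nbytes * 4), dtype=np.uint8)
    packed[:, :n] = codes
    packed = packed.reshape(m, nbytes, 4)
    shifted = (packed << np.array([0, 2, 4, 6], dtype=np.uint8)).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(shifted.tobytes())

    bim = pd.DataFrame(
        {
            "chr": variant_meta["chr"],
            "snp_id": variant_meta["snp_id"],
            "cm": 0,
            "bp": variant_meta["bp"],
            "a1": variant_meta["allele1"],
            "a2": variant_meta["allele2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {"fid": sample_ids, "iid": sample_ids, "pid": 0, "mid": 0, "sex": 0, "pheno": -9}
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_plink(prefix: str | Path) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Read .bed/.bim/.fam -> (dosage matrix, variant_meta, sample table)."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chr", "snp_id", "cm", "bp", "allele1", "allele2"],
        dtype={"snp_id": str, "allele1": str, "allele2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "pid", "mid", "sex", "pheno"], dtype={"iid": str},
    )
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise ValueError("not a PLINK .bed file (bad magic bytes)")
    if raw[2] != _SNP_MAJOR:
        raise ValueError("only SNP-major .bed files are supported")
    nbytes = (n + 3) // 4
    expected = 3 + nbytes * m
    if len(raw) != expected:
        raise ValueError(
            f".bed length {len(raw)} does not match bim/fam dimensions (expected {expected})"
        )
    data = np.frombuffer(raw[3:], dtype=np.uint8).reshape(m, nbytes)
    codes = np.stack([(data >> s) & 0b11 for s in (0, 2, 4, 6)], axis=2).reshape(m, nbytes * 4)
    G = _DECODE[codes[:, :n]].T.copy()
    return G, bim, fam


def write_genotypes_tsv(prefix: str | Path, genotypes: np.ndarray,
                        variant_meta: pd.DataFrame, sample_ids,
                        seed: int | None = None) -> None:
    """Transparent TSV fallback: <prefix>.geno.tsv + <prefix>.var.tsv."""
    prefix = Path(prefix)
    G = pd.DataFrame(np.asarray(genotypes, dtype=float),
                     columns=list(variant_meta["snp_id"]))
    G.insert(0, "sample_id", list(sample_ids))
    header = "\n".join(provenance_lines(seed)) + "\n"
    with open(f"{prefix}.geno.tsv", "w") as fh:
        fh.write(header)
        G.to_csv(fh, sep="\t", index=False, na_rep=MISSING_TOKEN)
    with open(f"{prefix}.var.tsv", "w") as fh:
        fh.write(header)
        variant_meta.to_csv(fh, sep="\t", index=False)


def read_genotypes_tsv(prefix: str | Path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    prefix = Path(prefix)
    geno = pd.read_csv(f"{prefix}.geno.tsv", sep="\t", comment="#",
                       na_values=[MISSING_TOKEN])
    vm = pd.read_csv(f"{prefix}.var.tsv", sep="\t", comment="#",
                     dtype={"snp_id": str, "allele1": str, "allele2": str})
    sample_ids = geno["sample_id"].astype(str).tolist()
    G = geno.drop(columns="sample_id").to_numpy(dtype=float)
    if G.shape[1] != len(vm):
        raise ValueError("genotype TSV and variant TSV disagree on variant count")
    return G, vm, sample_ids


def read_genotypes(path: str | Path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Auto-detect PLINK prefix vs TSV fallback prefix."""
    path = Path(path)
    if path.with_suffix(".bed").exists():
        G, bim, fam = read_plink(path)
        return G, bim, fam["iid"].tolist()
    if Path(f"{path}.geno.tsv").exists():
        return read_genotypes_tsv(path)
    raise FileNotFoundError(f"no genotype data found at prefix {path}")


def write_sumstats(path: str | Path, sumstats: pd.DataFrame,
                   seed: int | None = None) -> None:
    cols = ["snp_id", "chr", "bp", "effect_allele", "other_allele", "beta", "se", "p_value"]
    out = sumstats[cols].rename(columns={"effect_allele": "a1", "other_allele": "a2",
                                         "p_value": "p"})
    with open(path, "w") as fh:
        fh.write("\n".join(provenance_lines(seed)) + "\n")
        out.to_csv(fh, sep="\t", index=False)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"snp_id": str, "a1": str, "a2": str})
    return df.rename(columns={"a1": "effect_allele", "a2": "other_allele", "p": "p_value"})


def write_phenotypes(path: str | Path, table: pd.DataFrame, sample_ids,
                     seed: int | None = None) -> None:
    out = table.copy()
    out.insert(0, "sample_id", list(sample_ids))
    with open(path, "w") as fh:
        fh.write("\n".join(provenance_lines(seed)) + "\n")
        out.to_csv(fh, sep="\t", index=False, na_rep=MISSING_TOKEN)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=[MISSING_TOKEN],
                       dtype={"sample_id": str})


def write_density_map(path: str | Path, dmap: DensityMap) -> None:
    """Gridded TSV: a JSON header comment, then row-major density values."""
    header = {"x_min": dmap.x_min, "y_min": dmap.y_min, "cell_km": dmap.cell_km,
              "ny": dmap.values.shape[0], "nx": dmap.values.shape[1]}
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header, sort_keys=True) + "\n")
        np.savetxt(fh, dmap.values, delimiter="\t", fmt="%.6g")


def read_density_map(path: str | Path) -> DensityMap:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# "):
            raise ValueError("density map missing JSON header line")
        header = json.loads(first[2:])
        values = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if values.shape != (header["ny"], header["nx"]):
        raise ValueError("density map raster shape does not match header")
    return DensityMap(header["x_min"], header["y_min"], header["cell_km"], values)
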