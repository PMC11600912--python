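"""File formats: pedigree/phenotype CSV, PLINK-.raw-style genotypes,
variance-component text blocks, sparse matrix dumps and run manifests.

CSV dialect is fixed (comma, UTF-8, '.' decimal, mandatory header) to
eliminate locale drift.  Animal ids are opaque strings; 0 or empty means
an unknown parent.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genomic import MarkerSet
from .pedigree import Pedigree

__all__ = [
    "read_pedigree", "write_pedigree",
    "read_phenotypes", "write_phenotypes",
    "read_genotypes", "write_genotypes",
    "read_varcomp", "write_varcomp",
    "write_sparse_coord", "read_config",
    "write_herd", "write_manifest",
]

PHENO_COLS = ["animal", "parity", "value", "hys", "farm_type", "calving_year"]


def read_pedigree(path, strict_years: bool = False) -> Pedigree:
    df = pd.read_csv(path, dtype={"id": str, "sire": str, "dam": str})
    missing = {"id", "sire", "dam", "sex", "birth_year"} - set(df.columns)
    if missing:
        raise ValueError(f"pedigree file lacks columns {sorted(missing)}")
    return Pedigree.from_frame(df, strict_years=strict_years)


def write_pedigree(ped: Pedigree, path):
    ped.to_frame().to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"animal": str, "hys": str, "farm_type": str})
    missing = set(PHENO_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file lacks columns {sorted(missing)}")
    return df[PHENO_COLS]


def write_phenotypes(phen: pd.DataFrame, path):
    phen[PHENO_COLS].to_csv(path, index=False)


def read_genotypes(path) -> MarkerSet:
    """PLINK-.raw-like whitespace table: header `IID snp1 snp2 …`, one row
    per animal, dosages 0/1/2 or NA."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        if not header or header[0] != "IID":
            raise ValueError(f"{path}: first header field must be 'IID'")
        markers = header[1:]
        animals, rows = [], []
        for ln, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != len(markers) + 1:
                raise ValueError(f"{path}:{ln}: expected {len(markers) + 1} "
                                 f"fields, got {len(parts)}")
            animals.append(parts[0])
            row = []
            for k, v in enumerate(parts[1:], start=1):
                if v in ("NA", "nan", "."):
                    row.append(np.nan)
                elif v in ("0", "1", "2"):
                    row.append(float(v))
                else:
                    raise ValueError(
                        f"{path}:{ln}: invalid dosage {v!r} for marker "
                        f"{markers[k - 1]}")
            rows.append(row)
    return MarkerSet(animal_ids=animals, marker_ids=markers,
                     M=np.asarray(rows, dtype=float))


def write_genotypes(ms: MarkerSet, path):
    with open(path, "w") as fh:
        fh.write("IID " + " ".join(ms.marker_ids) + "\n")
        for a, row in zip(ms.animal_ids, ms.M):
            cells = " ".join("NA" if np.isnan(v) else str(int(v)) for v in row)
            fh.write(f"{a} {cells}\n")


def _write_block(fh, name, S):
    fh.write(f"[{name}]\n")
    for i in range(S.shape[0]):
        fh.write(" ".join(f"{S[i, j]:.10g}" for j in range(i + 1)) + "\n")


def write_varcomp(path, G0, R0, G0_se=None, R0_se=None):
    """Lower-triangle text blocks for the parity covariance matrices."""
    with open(path, "w") as fh:
        _write_block(fh, "G0", np.asarray(G0))
        _write_block(fh, "R0", np.asarray(R0))
        if G0_se is not None:
            _write_block(fh, "G0_SE", np.asarray(G0_se))
        if R0_se is not None:
            _write_block(fh, "R0_SE", np.asarray(R0_se))


def read_varcomp(path) -> dict:
    blocks: dict[str, list] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("["):
                name = line.strip("[]")
                blocks[name] = []
            else:
                blocks[name].append([float(v) for v in line.split()])
    out = {}
    for name, tri in blocks.items():
        n = len(tri)
        S = np.zeros((n, n))
        for i, row in enumerate(tri):
            for j, v in enumerate(row):
                S[i, j] = S[j, i] = v
        out[name] = S
    return out


def write_sparse_coord(mat, path):
    """Coordinate-format text dump (i j value per line, 0-based)."""
    coo = sp.coo_matrix(mat)
    with open(path, "w") as fh:
        fh.write(f"% {coo.shape[0]} {coo.shape[1]} {coo.nnz}\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i} {j} {v:.12g}\n")


def read_config(path) -> dict:
    """Flat key = value configuration; values coerced to int/float/bool
    where possible."""
    out = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected key = value")
            k, v = (s.strip() for s in line.split("=", 1))
            for cast in (int, float):
                try:
                    v = cast(v)
                    break
                except ValueError:
                    continue
            if v in ("true", "True"):
                v = True
            elif v in ("false", "False"):
                v = False
            out[k] = v
    return out


def write_herd(herd, outdir):
    """Write a synthetic herd as the four text files downstream stages read."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_pedigree(herd.pedigree, outdir / "pedigree.csv")
    write_phenotypes(herd.phenotypes, outdir / "phenotypes.csv")
    write_genotypes(herd.genotyped_markers(), outdir / "genotypes.raw")
    tv = herd.true_breeding_values.copy()
    tv.insert(0, "animal", tv.index)
    tv.to_csv(outdir / "true_values.csv", index=False)
    return outdir


def write_manifest(outdir, config: dict, seed=None, extra=None):
    """Machine-readable run manifest: config hash + seed make the run
    reproducible."""
    payload = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
               for k, v in config.items() if not callable(v)}
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()
    manifest = {"config": payload, "config_sha256": digest, "seed": seed}
    if extra:
        manifest.update(extra)
    path = Path(outdir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
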