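"""File formats, validation and provenance.

All tabular files are plain CSV with a single ``#``-prefixed metadata
header line recording the file kind, the run seed and the configuration
hash; the phylogeny is strict Newick. Missing values are serialized as
empty fields. Every writer's output is readable by its reader with value
equality.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
import json
import logging
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .biomass import CENSUS_COLUMNS, SpeciesPool
from .errors import ValidationError

log = logging.getLogger(__name__)


def config_hash(obj) -> str:
    """Short stable hash of a configuration mapping or dataclass.

    Output location and logging verbosity do not influence results and
    are excluded, so the hash identifies the scientific configuration.
    """
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    obj = {k: v for k, v in obj.items() if k not in ("out_dir", "verbosity")}
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def _header(kind: str, seed, cfg_hash: str, extra: dict | None = None) -> str:
    parts = [f"# forestdyn {kind}", f"seed={seed}", f"config={cfg_hash}"]
    for k, v in (extra or {}).items():
        parts.append(f"{k}={v}")
    return " ".join(parts) + "\n"


def write_csv(df: pd.DataFrame, path, kind: str, seed, cfg_hash: str,
              extra: dict | None = None, index: bool = True) -> None:
    path = Path(path)
    buf = _io.StringIO()
    buf.write(_header(kind, seed, cfg_hash, extra))
    df.to_csv(buf, index=index)
    path.write_text(buf.getvalue())


def read_csv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def _read_header_fields(path) -> dict:
    with open(path) as fh:
        first = fh.readline()
    out = {}
    if first.startswith("#"):
        for token in first.split():
            if "=" in token:
                k, v = token.split("=", 1)
                out[k] = v
    return out


# ---------------------------------------------------------------------------
# study round-trip


def write_study(study, outdir) -> Path:
    """Write a synthetic study as the file set the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = study.config
    h = config_hash(cfg)
    seed = cfg.seed

    write_csv(study.censuses[ [c for c in CENSUS_COLUMNS + ["agb_scale"] if c in study.censuses.columns] ],
              outdir / "censuses.csv", "census", seed, h, index=False)
    pa, pb, pcf = study.species_pool.pooled_height
    write_csv(study.species_pool.traits, outdir / "species.csv", "species", seed, h,
              extra={"pooled_a": pa, "pooled_b": pb, "pooled_cf": pcf})
    if study.species_pool.tree is not None:
        study.species_pool.tree.write(path=str(outdir / "phylogeny.nwk"), schema="newick",
                                      suppress_rooting=True)
    np.savetxt(outdir / "elevation.csv", study.landscape.corner_elevations, delimiter=",",
               header=_header("elevation", seed, h).strip("#\n "), comments="# ")
    write_csv(study.landscape.frame[["habitat"]], outdir / "habitat.csv", "habitat", seed, h)
    (outdir / "truth.json").write_text(json.dumps(study.truth, indent=1, sort_keys=True))
    cfgd = dataclasses.asdict(cfg)
    cfgd["embedded_effects"] = [list(e) for e in cfg.embedded_effects]
    (outdir / "simulation_config.json").write_text(json.dumps(cfgd, indent=1, sort_keys=True, default=str))
    return outdir


def read_census(path) -> pd.DataFrame:
    df = read_csv(path)
    missing = [c for c in CENSUS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: census table missing columns {missing}")
    return df


def read_species(path) -> SpeciesPool:
    hdr = _read_header_fields(path)
    df = read_csv(path).set_index("species")
    pooled = (float(hdr.get("pooled_a", 2.0)), float(hdr.get("pooled_b", 0.55)),
              float(hdr.get("pooled_cf", 1.0)))
    return SpeciesPool(df, pooled_height=pooled)


def read_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def read_elevation(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", comments="#", ndmin=2)


def read_habitat(path) -> pd.Series:
    df = read_csv(path)
    return df.set_index("quadrat")["habitat"]


# ---------------------------------------------------------------------------
# validation


def validate_bundle(censuses: pd.DataFrame, pool: SpeciesPool,
                    tree: dendropy.Tree | None) -> dendropy.Tree | None:
    """Cross-validate censuses against species table and phylogeny.

    Raises on alive stems below the 1 cm inclusion threshold, duplicate
    (tree, stem, census) keys, and census species missing from the
    species table or the tree. Tree tips absent from the censuses are
    pruned (logged). Returns the (possibly pruned) tree.
    """
    alive = censuses[censuses["status"] == "alive"]
    bad = alive[alive["dbh_cm"] < 1.0]
    if len(bad):
        rec = bad.iloc[0]
        raise ValidationError(
            f"alive stems with DBH < 1 cm violate the census inclusion rule; first: "
            f"tree {rec['tree_id']} stem {rec['stem_id']} census {rec['census']} "
            f"dbh={rec['dbh_cm']}")
    dup = censuses.duplicated(subset=["tree_id", "stem_id", "census"])
    if dup.any():
        rec = censuses[dup].iloc[0]
        raise ValidationError(
            f"duplicate (tree, stem, census) key: {rec['tree_id']}/{rec['stem_id']}/{rec['census']}")
    census_sp = set(censuses["species"].unique())
    missing = census_sp - set(pool.species)
    if missing:
        raise ValidationError(f"census species absent from species table: {sorted(missing)[:5]}")
    if tree is not None:
        tips = {t.label for t in tree.taxon_namespace}
        no_tip = census_sp - tips
        if no_tip:
            raise ValidationError(f"census species absent from phylogeny: {sorted(no_tip)[:5]}")
        extra = tips - set(pool.species)
        if extra:
            keep = [t for t in tree.taxon_namespace if t.label not in extra]
            tree = tree.extract_tree_with_taxa(taxa=keep)
            log.info("pruned %d phylogeny tips absent from the species pool", len(extra))
    return tree
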