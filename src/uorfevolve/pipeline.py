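"""Stage orchestration: run annotate/O-E/Kozak/BLS stages from a flat
config, write tidy TSVs plus a manifest, and summarize headline
statistics (including the canonical-vs-noncanonical Fisher test).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
from scipy import stats

from . import __version__
from .annotate import (
    composition_summary,
    exclude_uaugs_in_other_cds,
    find_and_classify_uaugs,
    load_transcripts,
    records_to_frame,
    select_longest_and_filter_utrs,
    write_records_bed,
)
from .kozak import build_pwmk, score_records
from .oe_stats import oe_ratio

SCHEMA_VERSION = 1

_KNOWN_KEYS = {
    "schema_version",
    "stages",
    "out_dir",
    "seed",
    "transcripts_tsv",
    "gff",
    "fasta",
    "maf",
    "tree",
    "sites_bed",
    "n_perm",
    "triplet",
    "positional_L",
    "expression_tsv",
    "validation_counts",
}

_STAGE_ORDER = ["annotate", "oe", "kozak", "bls", "report"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    stages: list[str]
    out_dir: str
    seed: int = 0
    transcripts_tsv: Optional[str] = None
    gff: Optional[str] = None
    fasta: Optional[str] = None
    maf: Optional[str] = None
    tree: Optional[str] = None
    sites_bed: Optional[str] = None
    n_perm: int = 1000
    triplet: str = "ATG"
    positional_L: int = 100
    expression_tsv: Optional[str] = None
    validation_counts: Optional[list[list[int]]] = None
    extras: dict = field(default_factory=dict)


def load_config(path) -> PipelineConfig:
    """Load and validate a JSON pipeline config (unknown keys error)."""
    with open(path) as fh:
        raw = json.load(fh)
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    version = raw.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {version}")
    return PipelineConfig(**raw)


def _header(cfg: PipelineConfig, **params) -> str:
    items = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    return f"# uorfevolve {__version__} seed={cfg.seed} {items}\n"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, **params) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg, **params))
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns (and writes) a manifest mapping stage -> output files with
    the parameters and seed used; every output TSV carries a
    provenance header line.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": {},
    }
    stages = [s for s in _STAGE_ORDER if s in cfg.stages]
    unknown = set(cfg.stages) - set(_STAGE_ORDER)
    if unknown:
        raise PipelineError(sorted(unknown)[0], "unknown stage")
    state: dict = {}
    for stage in stages:
        runner = _RUNNERS[stage]
        files = runner(cfg, out, state)
        manifest["stages"][stage] = {
            "files": [str(Path(f).relative_to(out)) for f in files]
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _require(cfg: PipelineConfig, stage: str, attr: str) -> str:
    value = getattr(cfg, attr)
    if value is None:
        raise PipelineError(stage, f"missing required input {attr!r}")
    if not Path(value).exists():
        raise PipelineError(stage, f"input file not found: {value}")
    return value


def _run_annotate(cfg, out: Path, state) -> list[Path]:
    if cfg.gff is not None:
        _require(cfg, "annotate", "gff")
        fasta = _require(cfg, "annotate", "fasta")
        models = load_transcripts(cfg.gff, fasta)
    else:
        tsv = _require(cfg, "annotate", "transcripts_tsv")
        models = load_transcripts(tsv)
    kept, report = select_longest_and_filter_utrs(models)
    records = []
    for m in kept:
        records.extend(find_and_classify_uaugs(m))
    records = exclude_uaugs_in_other_cds(records, models)
    state["models"] = kept
    state["records"] = records
    bed = out / "uaugs.bed"
    write_records_bed(records, bed)
    tsv_path = out / "uaugs.tsv"
    _write_tsv(records_to_frame(records), tsv_path, cfg)
    comp = out / "composition.tsv"
    _write_tsv(composition_summary({"sample": records}), comp, cfg)
    return [bed, tsv_path, comp]


def _run_oe(cfg, out: Path, state) -> list[Path]:
    if "models" not in state:
        raise PipelineError("oe", "missing upstream output from stage 'annotate'")
    seqs = [m.utr5_seq for m in state["models"]]
    res = oe_ratio(seqs, cfg.triplet, cfg.n_perm, cfg.seed)
    df = pd.DataFrame(
        [
            {
                "triplet": res.triplet,
                "scope": res.scope,
                "n_obs": res.n_obs,
                "n_exp_median": res.n_exp_median,
                "ratio": res.ratio,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "n_perm": res.n_perm,
            }
        ]
    )
    path = out / "oe.tsv"
    _write_tsv(df, path, cfg, n_perm=cfg.n_perm, triplet=cfg.triplet)
    state["oe"] = res
    return [path]


def _run_kozak(cfg, out: Path, state) -> list[Path]:
    if "models" not in state:
        raise PipelineError("kozak", "missing upstream output from stage 'annotate'")
    pwm = build_pwmk(state["models"])
    score_records(state.get("records", []), pwm)
    rows = []
    for row, pos in enumerate((-6, -5, -4, -3, -2, -1, 4)):
        rows.append(
            {"position": pos, **{b: pwm.probs[row, j] for j, b in enumerate("ACGT")}}
        )
    path = out / "kozak_pwm.tsv"
    _write_tsv(pd.DataFrame(rows), path, cfg, pseudocount=pwm.pseudocount)
    scores = out / "kozak_scores.tsv"
    _write_tsv(records_to_frame(state.get("records", [])), scores, cfg)
    return [path, scores]


def _run_bls(cfg, out: Path, state) -> list[Path]:
    from .conservation import (
        PhylogeneticTree,
        branch_length_score,
        parse_maf,
        presence_profile_from_maf,
    )

    maf = _require(cfg, "bls", "maf")
    tree_path = _require(cfg, "bls", "tree")
    sites_path = _require(cfg, "bls", "sites_bed")
    tree = PhylogeneticTree(Path(tree_path).read_text())
    blocks = parse_maf(maf)
    sites = pd.read_csv(
        sites_path, sep="\t", names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    reference = tree.species[0]
    rows = []
    for row in sites.itertuples(index=False):
        profile = presence_profile_from_maf(
            blocks, row.name, row.chrom, int(row.start), tree.species, reference
        )
        res = branch_length_score(profile, tree)
        rows.append({"site": row.name, "b0": res.b0, "bls": res.bls})
    path = out / "bls.tsv"
    _write_tsv(pd.DataFrame(rows), path, cfg)
    state["bls"] = rows
    return [path]


def _run_report(cfg, out: Path, state) -> list[Path]:
    report: dict = {}
    if "oe" in state:
        res = state["oe"]
        report["oe_ratio"] = res.ratio
        report["oe_ci"] = [res.ci_low, res.ci_high]
    if "bls" in state:
        import numpy as np

        report["mean_bls"] = float(np.mean([r["bls"] for r in state["bls"]]))
    if cfg.validation_counts is not None:
        odds, p = fisher_validation(cfg.validation_counts)
        report["fisher_odds_ratio"] = odds
        report["fisher_p"] = p
    path = out / "report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return [path]


_RUNNERS = {
    "annotate": _run_annotate,
    "oe": _run_oe,
    "kozak": _run_kozak,
    "bls": _run_bls,
    "report": _run_report,
}


def fisher_validation(
    table, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 validation-outcome table.

    Rows: canonical / noncanonical uORF variants; columns: repressive
    uORF allele yes/no.  Returns (odds ratio, p).
    """
    odds, p = stats.fisher_exact(table, alternative=alternative)
    return float(odds), float(p)
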