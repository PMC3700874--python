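"""End-to-end orchestration: chemistry → energetics, OTUs → community stats.

A :class:`RunConfig` fully determines a run (inputs or synthetic specs,
censoring and thermodynamic assumptions, statistical parameters, seeds);
it is serialized into the output directory alongside every product so any
output can be reproduced from its snapshot.  The CLI wraps the same
stages as subcommands.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import click
import pandas as pd
import yaml

from . import bioenergetics as be
from . import commstats as cs
from . import geochem as gc
from . import otu as otumod
from . import synthetic_data as synth

__all__ = ["RunConfig", "RunReport", "run_pipeline", "write_report", "read_report", "cli"]

log = logging.getLogger("aquibiome")

CLASS_PAIRS = (("HS", "LS"), ("HS", "NS"), ("LS", "NS"))
NOT_TESTABLE = "not testable: group too small"


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run.

    ``wells``: "reference" (bundled 25-well survey), "synthetic", or a
    path to a chemistry table.  ``otu_source``: "synthetic", a FASTA
    path (clustered at ``cutoff``), or an OTU-table TSV path.
    """

    outdir: str = "aquibiome_out"
    seed: int = 0
    wells: str = "reference"
    otu_source: str = "synthetic"
    censoring: str = "limit"
    dG_min: float = 10.0
    sulfide_molal: float = 1.0e-5
    fe2_molal: float = 1.0e-5
    conductivity_k: float = 1.6e-5
    cutoff: float = 0.03
    distance_mode: str = "aligned"
    n_perms: int = 999
    n_restarts: int = 20
    class_overrides: Mapping[str, str] = field(default_factory=dict)

    def energy_config(self) -> be.EnergyConfig:
        return be.EnergyConfig(
            dG_min=self.dG_min,
            sulfide_molal=self.sulfide_molal,
            fe2_molal=self.fe2_molal,
            censoring=self.censoring,
            conductivity_k=self.conductivity_k,
        )

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["class_overrides"] = dict(self.class_overrides)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class RunReport:
    """Outputs of a pipeline run: file paths plus the numeric summary."""

    config: RunConfig
    outputs: dict[str, str]
    summary: dict[str, Any]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _timed(stage: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                log.error("stage %s: failed after %.2fs", stage, dt)
                raise StageError(stage, exc) from exc
            log.info("stage %s: done in %.2fs", stage, dt)
            return False

    return _Ctx()


def _load_wells(config: RunConfig) -> list[gc.WellChemistry]:
    if config.wells == "reference":
        return gc.load_reference_wells()
    if config.wells == "synthetic":
        return synth.gen_chemistry(synth.ChemistrySpec(seed=config.seed))
    return gc.read_well_table(config.wells)


def _well_classes(
    wells: Sequence[gc.WellChemistry], overrides: Mapping[str, str]
) -> dict[str, str]:
    classes: dict[str, str] = {}
    for w in wells:
        if w.well_id in overrides:
            classes[w.well_id] = overrides[w.well_id]
            continue
        try:
            classes[w.well_id] = gc.classify_sulfate(w.so4).value
        except ValueError:
            classes[w.well_id] = "unclassified"
    return classes


def energy_report(
    wells: Sequence[gc.WellChemistry],
    config: be.EnergyConfig,
    classes: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-well × per-reaction energy table (the energy-report schema)."""
    classes = classes or {}
    rows = []
    for chem in wells:
        for rxn in be.reaction_catalog():
            res = be.available_energy(rxn, chem, config)
            rows.append(
                {
                    "well_id": res.well_id,
                    "class": classes.get(chem.well_id, ""),
                    "reaction": res.reaction,
                    "dG0_T": res.dG0_T,
                    "lnQ": res.ln_q,
                    "dG_r": res.dG_r,
                    "dG_A": res.dG_A,
                    "per_electron": res.per_electron,
                    "viable": res.viable,
                    "ok": res.ok,
                    "missing": ";".join(res.missing),
                    "assumptions": ";".join(res.assumptions),
                }
            )
    return pd.DataFrame(rows)


def _load_otu_table(config: RunConfig) -> otumod.OtuTable:
    if config.otu_source == "synthetic":
        return synth.gen_otu_table(synth.CommunitySpec(seed=config.seed))
    path = Path(config.otu_source)
    if path.suffix.lower() in (".fa", ".fasta", ".fna"):
        seqs = otumod.read_fasta(path)
        table, _ = otumod.cluster_average_neighbor(
            seqs, cutoff=config.cutoff, mode=config.distance_mode
        )
        return table
    return otumod.OtuTable.from_tsv(path)


def anosim_class_table(
    table: otumod.OtuTable, n_perms: int, seed: int
) -> pd.DataFrame:
    """ANOSIM between sulfate-zone pairs, per fraction (survey layout).

    Rows HS-LS, HS-NS, LS-NS; per fraction an R and a p column.  Pairs
    where either zone has fewer than two samples in that fraction are
    reported as explicitly not testable rather than omitted.
    """
    meta = table.sample_meta
    if meta is None:
        raise ValueError("OTU table has no sample metadata (fraction/class)")
    fractions = sorted(meta["fraction"].unique())
    rows = []
    for pair in CLASS_PAIRS:
        row: dict[str, Any] = {"pair": f"{pair[0]}-{pair[1]}"}
        for frac in fractions:
            sel = meta[(meta["fraction"] == frac) & (meta["sulfate_class"].isin(pair))]
            sizes = sel["sulfate_class"].value_counts()
            if len(sel) < 4 or any(sizes.get(c, 0) < 2 for c in pair):
                row[f"R_{frac}"] = NOT_TESTABLE
                row[f"p_{frac}"] = NOT_TESTABLE
                continue
            sub = table.subset_samples(list(sel.index))
            dm = cs.bray_curtis(sub)
            groups = {s: meta.loc[s, "sulfate_class"] for s in sub.samples}
            res = cs.anosim(dm, groups, n_perms=n_perms, seed=seed)
            row[f"R_{frac}"] = round(res.R, 4)
            row[f"p_{frac}"] = res.p
        rows.append(row)
    return pd.DataFrame(rows).set_index("pair")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute chemistry → energetics → community statistics end to end.

    Deterministic for a fixed config: seeded stages derive their streams
    from ``config.seed``.  Every output lands in ``config.outdir`` next
    to a config snapshot.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    summary: dict[str, Any] = {}

    with _timed("chemistry"):
        wells = _load_wells(config)
        classes = _well_classes(wells, config.class_overrides)
        chem_path = outdir / "chemistry.tsv"
        gc.write_well_table(wells, chem_path)
        class_df = pd.DataFrame(
            sorted(classes.items()), columns=["well_id", "sulfate_class"]
        )
        class_path = outdir / "sulfate_classes.tsv"
        class_df.to_csv(class_path, sep="\t", index=False)
        outputs["chemistry"] = str(chem_path)
        outputs["sulfate_classes"] = str(class_path)
        summary["n_wells"] = len(wells)
        summary["class_counts"] = {
            c: int((class_df["sulfate_class"] == c).sum())
            for c in sorted(class_df["sulfate_class"].unique())
        }

    with _timed("energy"):
        e_cfg = config.energy_config()
        edf = energy_report(wells, e_cfg, classes)
        energy_path = outdir / "energy_report.tsv"
        edf.to_csv(energy_path, sep="\t", index=False)
        outputs["energy_report"] = str(energy_path)
        ok = edf[edf["ok"]]
        summary["dG_A_ranges"] = {
            rxn: [float(g["dG_A"].min()), float(g["dG_A"].max())]
            for rxn, g in ok.groupby("reaction")
        }
        thresholds = {}
        for chem in wells:
            try:
                thresholds[chem.well_id] = be.h2_threshold_aom(chem, e_cfg)
            except ValueError:
                continue
        thr_path = outdir / "aom_h2_thresholds.tsv"
        pd.DataFrame(
            sorted(thresholds.items()), columns=["well_id", "h2_threshold_nM"]
        ).to_csv(thr_path, sep="\t", index=False)
        outputs["aom_h2_thresholds"] = str(thr_path)
        summary["n_wells_with_aom_threshold"] = len(thresholds)

    with _timed("otu"):
        table = _load_otu_table(config)
        otu_path = outdir / "otu_table.tsv"
        table.to_tsv(otu_path)
        outputs["otu_table"] = str(otu_path)
        if table.sample_meta is not None:
            meta_path = outdir / "otu_sample_meta.tsv"
            table.sample_meta.to_csv(meta_path, sep="\t", index_label="sample")
            outputs["otu_sample_meta"] = str(meta_path)
        summary["n_samples"] = len(table.samples)
        summary["n_otus"] = len(table.otus)

    with _timed("stats"):
        stats_summary = community_stats(
            table, outdir, outputs,
            n_perms=config.n_perms, n_restarts=config.n_restarts, seed=config.seed,
        )
        summary.update(stats_summary)

    with _timed("report"):
        config.to_yaml(outdir / "config_snapshot.yaml")
        outputs["config_snapshot"] = str(outdir / "config_snapshot.yaml")
        report_path = outdir / "summary.json"
        with open(report_path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        outputs["summary"] = str(report_path)

    return RunReport(config, outputs, summary)


def community_stats(
    table: otumod.OtuTable,
    outdir: Path,
    outputs: dict[str, str],
    n_perms: int,
    n_restarts: int,
    seed: int,
) -> dict[str, Any]:
    """Distance, ANOSIM, SIMPER, NMDS and richness products for one table."""
    summary: dict[str, Any] = {}
    dm = cs.bray_curtis(table)
    dm_path = outdir / "bray_curtis.tsv"
    dm.to_tsv(dm_path)
    outputs["bray_curtis"] = str(dm_path)

    meta = table.sample_meta
    if meta is not None and "fraction" in meta:
        frac_groups = {s: str(meta.loc[s, "fraction"]) for s in table.samples}
        counts = pd.Series(list(frac_groups.values())).value_counts()
        if len(counts) == 2 and (counts >= 2).all():
            res = cs.anosim(dm, frac_groups, n_perms=n_perms, seed=seed)
            summary["anosim_fraction"] = {
                "R": res.R, "p": res.p, "band": res.band.value,
                "n_perms": res.n_perms,
            }
            att = [s for s, g in frac_groups.items() if g == "ATT"]
            sus = [s for s, g in frac_groups.items() if g == "SUS"]
            if att and sus:
                rich = otumod.shared_richness(table, att, sus)
                pd.DataFrame([rich]).to_csv(
                    outdir / "shared_richness.tsv", sep="\t", index=False
                )
                outputs["shared_richness"] = str(outdir / "shared_richness.tsv")
                summary["shared_richness_fraction"] = rich
                sim = cs.simper(table, att, sus)
                sim.table.to_csv(outdir / "simper_fraction.tsv", sep="\t",
                                 index_label="otu")
                outputs["simper_fraction"] = str(outdir / "simper_fraction.tsv")
                summary["simper_top_otu"] = str(sim.table.index[0])

        anosim_tbl = anosim_class_table(table, n_perms=n_perms, seed=seed)
        anosim_path = outdir / "anosim_classes.tsv"
        anosim_tbl.to_csv(anosim_path, sep="\t")
        outputs["anosim_classes"] = str(anosim_path)

    if len(table.samples) >= 4:
        ord_res = cs.nmds(dm, n_restarts=n_restarts, seed=seed)
        nmds_path = outdir / "nmds_coordinates.tsv"
        with open(nmds_path, "w") as fh:
            fh.write(f"# stress={ord_res.stress:.6f} converged={ord_res.converged}\n")
            ord_res.coordinates.to_csv(fh, sep="\t", index_label="sample")
        outputs["nmds"] = str(nmds_path)
        summary["nmds_stress"] = ord_res.stress
    return summary


def write_report(report: RunReport, path: str | Path) -> None:
    """Serialize a RunReport (config, outputs, summary) to JSON."""
    with open(path, "w") as fh:
        json.dump(
            {
                "config": report.config.to_dict(),
                "outputs": report.outputs,
                "summary": report.summary,
            },
            fh,
            indent=2,
            sort_keys=True,
        )


def read_report(path: str | Path) -> RunReport:
    with open(path) as fh:
        d = json.load(fh)
    return RunReport(RunConfig.from_dict(d["config"]), d["outputs"], d["summary"])


# ---------------------------------------------------------------------------
# CLI


def _setup_logging(verbose: bool) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def _config_from_opts(config, seed, outdir, **overrides) -> RunConfig:
    base = RunConfig.from_yaml(config) if config else RunConfig()
    updates = {k: v for k, v in overrides.items() if v is not None}
    if seed is not None:
        updates["seed"] = seed
    if outdir is not None:
        updates["outdir"] = outdir
    return dataclasses.replace(base, **updates)


common_opts = [
    click.option("--config", type=click.Path(exists=True), default=None,
                 help="YAML run config."),
    click.option("--seed", type=int, default=None),
    click.option("--outdir", type=click.Path(), default=None),
    click.option("--verbose/--quiet", default=True),
]


def _with_common(f):
    for opt in reversed(common_opts):
        f = opt(f)
    return f


@click.group()
def cli() -> None:
    """Groundwater bioenergetics and community-structure analysis."""


@cli.command("all")
@_with_common
def cmd_all(config, seed, outdir, verbose):
    """Run the full pipeline (chemistry → energy → OTUs → stats)."""
    _setup_logging(verbose)
    cfg = _config_from_opts(config, seed, outdir)
    report = run_pipeline(cfg)
    write_report(report, Path(cfg.outdir) / "run_report.json")
    click.echo(json.dumps(report.summary, indent=2, sort_keys=True))


@cli.command("synth")
@_with_common
def cmd_synth(config, seed, outdir, verbose):
    """Generate synthetic chemistry and OTU tables."""
    _setup_logging(verbose)
    cfg = _config_from_opts(config, seed, outdir, wells="synthetic",
                            otu_source="synthetic")
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    wells = synth.gen_chemistry(synth.ChemistrySpec(seed=cfg.seed))
    gc.write_well_table(wells, out / "synthetic_chemistry.tsv")
    table = synth.gen_otu_table(synth.CommunitySpec(seed=cfg.seed))
    table.to_tsv(out / "synthetic_otu_table.tsv")
    table.sample_meta.to_csv(out / "synthetic_otu_sample_meta.tsv", sep="\t",
                             index_label="sample")
    click.echo(f"wrote synthetic tables to {out}")


@cli.command("chem")
@click.option("--wells", default=None, help="chemistry table path, 'reference' or 'synthetic'")
@_with_common
def cmd_chem(wells, config, seed, outdir, verbose):
    """Normalize a chemistry table and classify wells by sulfate."""
    _setup_logging(verbose)
    cfg = _config_from_opts(config, seed, outdir, wells=wells)
    recs = _load_wells(cfg)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    gc.write_well_table(recs, out / "chemistry.tsv")
    classes = _well_classes(recs, cfg.class_overrides)
    pd.DataFrame(sorted(classes.items()), columns=["well_id", "sulfate_class"]).to_csv(
        out / "sulfate_classes.tsv", sep="\t", index=False
    )
    click.echo(f"{len(recs)} wells → {out}")


@cli.command("energy")
@click.option("--wells", default=None)
@_with_common
def cmd_energy(wells, config, seed, outdir, verbose):
    """Available-energy report for every well × reaction."""
    _setup_logging(verbose)
    cfg = _config_from_opts(config, seed, outdir, wells=wells)
    recs = _load_wells(cfg)
    classes = _well_classes(recs, cfg.class_overrides)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    edf = energy_report(recs, cfg.energy_config(), classes)
    edf.to_csv(out / "energy_report.tsv", sep="\t", index=False)
    click.echo(f"energy report for {len(recs)} wells → {out / 'energy_report.tsv'}")


@cli.command("otu")
@click.argument("fasta", type=click.Path(exists=True))
@_with_common
def cmd_otu(fasta, config, seed, outdir, verbose):
    """Cluster a FASTA clone library into an OTU table."""
    _setup_logging(verbose)
    cfg = _config_from_opts(config, seed, outdir, otu_source=fasta)
    table = _load_otu_table(cfg)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_tsv(out / "otu_table.tsv")
    click.echo(f"{len(table.samples)} samples × {len(table.otus)} OTUs → {out}")


@cli.command("stats")
@click.argument("otu_table", type=click.Path(exists=True))
@click.option("--meta", type=click.Path(exists=True), default=None,
              help="sample metadata TSV (sample, well_id, fraction, sulfate_class)")
@_with_common
def cmd_stats(otu_table, meta, config, seed, outdir, verbose):
    """Community statistics for an existing OTU table."""
    _setup_logging(verbose)
    cfg = _config_from_opts(config, seed, outdir)
    meta_df = (
        pd.read_csv(meta, sep="\t", index_col="sample") if meta else None
    )
    table = otumod.OtuTable.from_tsv(otu_table, sample_meta=meta_df)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    summary = community_stats(
        table, out, outputs, n_perms=cfg.n_perms,
        n_restarts=cfg.n_restarts, seed=cfg.seed,
    )
    click.echo(json.dumps(summary, indent=2, sort_keys=True, default=str))


if __name__ == "__main__":
    cli()
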