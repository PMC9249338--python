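"""Configuration-driven orchestration of all analysis stages.

A run is described by a :class:`RunConfig` (usually loaded from YAML), names
a subset of stages — consequences, nmd, contacts, hbonds, sasa, sites,
pseudogenes — and produces a :class:`RunReport` plus TSV/JSON outputs with a
provenance block (parameter values, input checksums, tool version).  Stage
failures abort dependent stages but leave independent stages running.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .genemodel import Sequence, load_transcript, read_fasta, translate_cds
from .mutate import (
    IntronicVariantError,
    parse_hgvs_c,
    predict_consequence,
    read_variant_table,
    summarize_consequences,
    write_consequence_table,
)
from .nmd import (
    DEFAULT_THRESHOLD_NT,
    NmdCall,
    NmdCategory,
    classify_nmd,
    summarize_nmd,
    write_nmd_table,
)
from .pseudogene import pseudogene_rescue_report
from .structcontact import (
    classify_mutation_sites,
    contact_profile,
    find_contacts,
    find_hbonds,
    read_structure,
    shrake_rupley_sasa,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "write_report"]

logger = logging.getLogger("ribovar")

ALL_STAGES = ("consequences", "nmd", "contacts", "hbonds", "sasa", "sites", "pseudogenes")
_SEQ_STAGES = {"consequences", "nmd"}
_STRUCT_STAGES = {"contacts", "hbonds", "sasa", "sites"}


@dataclass
class RunConfig:
    outdir: Path
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    # sequence-side inputs
    transcript_fasta: Path | None = None
    exon_table: Path | None = None
    cds_start: int | None = None
    cds_end: int | None = None
    variants: Path | None = None
    # structure-side inputs
    structures: dict[str, Path] = field(default_factory=dict)  # state -> file
    query_chain: str = "A"
    chain_roles: dict[str, str] = field(default_factory=dict)
    mutation_residues: list[int] = field(default_factory=list)
    # pseudogene inputs
    pseudogenes: Path | None = None
    reference_protein: Path | None = None
    # parameters
    contact_cutoff: float = 4.0
    hbond_dist: float = 3.5
    hbond_angle: float = 120.0
    nmd_threshold: int = DEFAULT_THRESHOLD_NT
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        base = Path(path).parent
        def _p(key):
            return (base / raw[key]) if raw.get(key) else None
        structures = {
            state: base / f for state, f in (raw.get("structures") or {}).items()
        }
        return cls(
            outdir=Path(raw.get("outdir", "ribovar_out")),
            stages=raw.get("stages", list(ALL_STAGES)),
            transcript_fasta=_p("transcript_fasta"),
            exon_table=_p("exon_table"),
            cds_start=raw.get("cds_start"),
            cds_end=raw.get("cds_end"),
            variants=_p("variants"),
            structures=structures,
            query_chain=raw.get("query_chain", "A"),
            chain_roles=raw.get("chain_roles", {}) or {},
            mutation_residues=raw.get("mutation_residues", []) or [],
            pseudogenes=_p("pseudogenes"),
            reference_protein=_p("reference_protein"),
            contact_cutoff=raw.get("contact_cutoff", 4.0),
            hbond_dist=raw.get("hbond_dist", 3.5),
            hbond_angle=raw.get("hbond_angle", 120.0),
            nmd_threshold=raw.get("nmd_threshold", DEFAULT_THRESHOLD_NT),
            gap_open=raw.get("gap_open", 10.0),
            gap_extend=raw.get("gap_extend", 0.5),
        )


@dataclass
class RunReport:
    consequence_table: pd.DataFrame | None = None
    consequence_distribution: pd.DataFrame | None = None
    nmd_calls: list[NmdCall] | None = None
    nmd_fractions: dict[str, float] | None = None
    contact_tables: dict[str, pd.DataFrame] | None = None
    contact_profile_table: pd.DataFrame | None = None
    hbond_tables: dict[str, pd.DataFrame] | None = None
    sasa_tables: dict[str, pd.DataFrame] | None = None
    site_report: pd.DataFrame | None = None
    pseudogene_table: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _provenance(config: RunConfig) -> dict:
    inputs = {}
    for label, p in [
        ("transcript_fasta", config.transcript_fasta),
        ("exon_table", config.exon_table),
        ("variants", config.variants),
        ("pseudogenes", config.pseudogenes),
        ("reference_protein", config.reference_protein),
        *[(f"structure_{s}", p) for s, p in sorted(config.structures.items())],
    ]:
        if p is not None:
            p = Path(p)
            inputs[label] = {
                "path": str(p),
                "sha256": _sha256(p) if p.exists() else None,
            }
    return {
        "tool": "ribovar",
        "version": __version__,
        "parameters": {
            "contact_cutoff": config.contact_cutoff,
            "hbond_dist": config.hbond_dist,
            "hbond_angle": config.hbond_angle,
            "nmd_threshold": config.nmd_threshold,
            "gap_open": config.gap_open,
            "gap_extend": config.gap_extend,
            "query_chain": config.query_chain,
        },
        "inputs": inputs,
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the requested stages in dependency order.

    A stage failure is recorded in ``report.errors`` and aborts its
    dependents (nmd needs consequences; sites need contacts and sasa) without
    stopping independent stages.
    """
    report = RunReport(provenance=_provenance(config))
    stages = set(config.stages)

    model = None
    consequences = None
    if stages & _SEQ_STAGES:
        try:
            cdna = read_fasta(config.transcript_fasta)[0]
            model = load_transcript(
                cdna, config.exon_table, config.cds_start, config.cds_end
            )
        except Exception as exc:
            logger.error("[transcript] %s", exc)
            for s in stages & _SEQ_STAGES:
                report.errors[s] = f"transcript loading failed: {exc}"
            stages -= _SEQ_STAGES

    if "consequences" in stages:
        try:
            table = read_variant_table(config.variants)
            consequences = []
            splice_ids = []
            for row in table.itertuples():
                try:
                    v = parse_hgvs_c(row.hgvs_c)
                except IntronicVariantError:
                    splice_ids.append((row.variant_id, row.hgvs_c))
                    continue
                consequences.append((row.variant_id, predict_consequence(model, v)))
            report.consequence_table = _consequence_frame(consequences, splice_ids)
            if consequences:
                report.consequence_distribution = summarize_consequences(
                    [c for _, c in consequences]
                )
            report.provenance["n_variants"] = len(table)
            report.provenance["n_splice_rejected"] = len(splice_ids)
            logger.info(
                "[consequences] %d variants (%d splice-site)",
                len(table),
                len(splice_ids),
            )
        except Exception as exc:
            logger.error("[consequences] %s", exc)
            report.errors["consequences"] = str(exc)
            consequences = None

    if "nmd" in stages:
        if consequences is None:
            report.errors.setdefault("nmd", "consequence stage did not run")
        else:
            calls = [
                classify_nmd(model, cons, vid, threshold_nt=config.nmd_threshold)
                for vid, cons in consequences
            ]
            # splice-site variants have no transcript-level consequence
            calls += [
                NmdCall(vid, NmdCategory.NOT_APPLICABLE, None, None, None, config.nmd_threshold)
                for vid in report.consequence_table.loc[
                    report.consequence_table["klass"] == "SPLICE", "variant_id"
                ]
            ]
            report.nmd_calls = calls
            report.nmd_fractions = summarize_nmd(calls)
            logger.info("[nmd] %s", report.nmd_fractions)

    structures = {}
    if stages & _STRUCT_STAGES:
        for state, path in sorted(config.structures.items()):
            try:
                structures[state] = read_structure(path, state)
            except Exception as exc:
                logger.error("[structures] %s: %s", path, exc)
                for s in stages & _STRUCT_STAGES:
                    report.errors.setdefault(s, f"structure {state} failed: {exc}")
        if not structures:
            for s in stages & _STRUCT_STAGES:
                report.errors.setdefault(s, "no structures loaded")
            stages -= _STRUCT_STAGES

    profile = None
    if "contacts" in stages and structures:
        all_records = []
        tables = {}
        for state, st_model in sorted(structures.items()):
            records = find_contacts(
                st_model, config.query_chain, cutoff=config.contact_cutoff
            )
            all_records.extend(records)
            tables[state] = pd.DataFrame(
                [
                    {
                        "query_res": r.query_res,
                        "query_atom": r.query_atom,
                        "partner_chain": r.partner_chain,
                        "partner_res": r.partner_res,
                        "partner_atom": r.partner_atom,
                        "distance": round(r.distance, 2),
                    }
                    for r in records
                ]
            )
            logger.info("[contacts] state %s: %d pairs", state, len(records))
        query_residues = sorted(
            {
                res
                for st_model in structures.values()
                for res in st_model.residues(config.query_chain)
            }
        )
        profile = contact_profile(
            all_records, sorted(structures), query_residues=query_residues
        )
        report.contact_tables = tables
        report.contact_profile_table = profile.to_frame()

    if "hbonds" in stages and structures:
        tables = {}
        for state, st_model in sorted(structures.items()):
            bonds = find_hbonds(
                st_model,
                config.query_chain,
                dist_cutoff=config.hbond_dist,
                angle_cutoff=config.hbond_angle,
            )
            tables[state] = pd.DataFrame(
                [
                    {
                        "donor_res": b.donor_res,
                        "donor_atom": b.donor_atom,
                        "acceptor_chain": b.acceptor_chain,
                        "acceptor_res": b.acceptor_res,
                        "acceptor_atom": b.acceptor_atom,
                        "distance": round(b.distance, 2),
                        "angle": round(b.angle, 1) if b.angle is not None else "",
                    }
                    for b in bonds
                ]
            )
        report.hbond_tables = tables

    sasa_by_state = {}
    if "sasa" in stages and structures:
        tables = {}
        for state, st_model in sorted(structures.items()):
            sasa = shrake_rupley_sasa(st_model)
            sasa_by_state[state] = sasa
            tables[state] = pd.DataFrame(
                [
                    {"chain": c, "residue": r, "sasa": round(v, 2)}
                    for (c, r), v in sorted(sasa.items())
                ]
            )
        report.sasa_tables = tables

    if "sites" in stages and structures:
        if profile is None:
            report.errors.setdefault("sites", "contacts stage did not run")
        else:
            residues = config.mutation_residues or sorted(
                {
                    res
                    for st_model in structures.values()
                    for res in st_model.residues(config.query_chain)
                }
            )
            resolved = {
                res
                for st_model in structures.values()
                for res in st_model.residues(config.query_chain)
            }
            report.site_report = classify_mutation_sites(
                profile,
                sasa_by_state,
                residues,
                config.query_chain,
                chain_roles=config.chain_roles,
                resolved_residues=resolved,
            )

    if "pseudogenes" in stages:
        try:
            ref = read_fasta(config.reference_protein, "PROTEIN")[0]
            rows = []
            for pg in read_fasta(config.pseudogenes, "DNA"):
                rep = pseudogene_rescue_report(
                    pg, ref, gap_open=config.gap_open, gap_extend=config.gap_extend
                )
                rows.append(
                    {
                        "pseudogene": pg.id,
                        "frame": rep.frame,
                        "identity_pct": round(rep.alignment.identity_pct, 1),
                        "similarity_pct": round(rep.alignment.similarity_pct, 1),
                        "gaps_pct": round(rep.alignment.gaps_pct, 1),
                        "internal_stops": rep.internal_stops,
                        "n_diff_positions": len(rep.diff_positions),
                    }
                )
            report.pseudogene_table = pd.DataFrame(rows)
            logger.info("[pseudogenes] %d sequences", len(rows))
        except Exception as exc:
            logger.error("[pseudogenes] %s", exc)
            report.errors["pseudogenes"] = str(exc)

    return report


def _consequence_frame(consequences, splice_ids) -> pd.DataFrame:
    rows = [
        {
            "variant_id": vid,
            "hgvs_c": c.variant.raw,
            "klass": c.klass.value,
            "mutant_length": c.mutant_length,
            "ptc_c_pos": c.ptc_c_pos if c.ptc_c_pos is not None else "",
            "length_delta_nt": c.length_delta_nt,
        }
        for vid, c in consequences
    ] + [
        {
            "variant_id": vid,
            "hgvs_c": hgvs,
            "klass": "SPLICE",
            "mutant_length": "",
            "ptc_c_pos": "",
            "length_delta_nt": "",
        }
        for vid, hgvs in splice_ids
    ]
    return pd.DataFrame(
        rows,
        columns=["variant_id", "hgvs_c", "klass", "mutant_length", "ptc_c_pos", "length_delta_nt"],
    )


def write_report(report: RunReport, outdir: str | Path) -> list[Path]:
    """Write all computed tables as TSV plus a JSON + plain-text summary.

    Percentages are formatted to 1 decimal, distances to 2; stages that did
    not run appear as explicit nulls in the JSON, never as phantom tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _tsv(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        written.append(path)

    if report.consequence_table is not None:
        _tsv(report.consequence_table, "consequences.tsv")
    if report.consequence_distribution is not None:
        dist = report.consequence_distribution.copy()
        dist["percent"] = dist["percent"].map(lambda v: f"{v:.1f}")
        _tsv(dist, "consequence_distribution.tsv")
    if report.nmd_calls is not None:
        write_nmd_table(report.nmd_calls, outdir / "nmd_calls.tsv")
        written.append(outdir / "nmd_calls.tsv")
    for name, tables in [
        ("contacts", report.contact_tables),
        ("hbonds", report.hbond_tables),
        ("sasa", report.sasa_tables),
    ]:
        if tables is not None:
            for state, df in sorted(tables.items()):
                _tsv(df, f"{name}_state_{state}.tsv")
    if report.contact_profile_table is not None:
        _tsv(report.contact_profile_table, "contact_profile.tsv")
    if report.site_report is not None:
        _tsv(report.site_report, "site_report.tsv")
    if report.pseudogene_table is not None:
        _tsv(report.pseudogene_table, "pseudogene_stats.tsv")

    summary = {
        "provenance": report.provenance,
        "nmd_fractions_pct": (
            {k: round(v, 1) for k, v in report.nmd_fractions.items()}
            if report.nmd_fractions
            else None
        ),
        "consequence_distribution": (
            {
                row["klass"]: {"count": int(row["count"]), "percent": round(row["percent"], 1)}
                for _, row in report.consequence_distribution.iterrows()
            }
            if report.consequence_distribution is not None
            else None
        ),
        "pseudogenes": (
            report.pseudogene_table.to_dict(orient="records")
            if report.pseudogene_table is not None
            else None
        ),
        "errors": report.errors or None,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(outdir / "summary.json")

    lines = [f"ribovar {__version__} run summary"]
    if report.nmd_fractions:
        lines.append(
            "NMD fractions: "
            + ", ".join(f"{k}={v:.1f}%" for k, v in sorted(report.nmd_fractions.items()))
        )
    if report.errors:
        lines += [f"stage {s} FAILED: {msg}" for s, msg in report.errors.items()]
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    written.append(outdir / "summary.txt")
    return written


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper()),
        format="%(levelname)s %(message)s",
    )
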