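"""Deterministic fixture generator with known ground truth for every stage.

The generated bundle emulates the study conditions of the RPS19/eS19
analysis: a 6-exon transcript coding a 145-aa protein, a 64-variant cohort
with planted consequence classes and NMD categories (30 escape / 19 degrade /
15 not-applicable), toy two-chain structures across three pseudo assembly
states with planted contact and H-bond counts (including a 45-atom-pair
hotspot residue contacting two RNA residues, the R62/C1542-U1543 analog),
and a pseudogene set degraded to a ladder of target identities whose top
member sits at 90.4%.

Everything is driven by one integer seed; per-generator substreams are
derived at fixed offsets so adding a generator never perturbs existing
fixtures, and regenerating with the same seed is byte-identical.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import pandas as pd

from .genemodel import (
    STANDARD_CODE,
    Sequence,
    TranscriptModel,
    write_fasta,
)
from .mutate import (
    ConsequenceClass,
    IntronicVariantError,
    parse_hgvs_c,
    predict_consequence,
)
from .nmd import NmdCategory, classify_nmd
from .structcontact import AtomRecord, StructureModel

__all__ = [
    "FixtureBundle",
    "PlantedContact",
    "PlantedHBond",
    "make_toy_transcript",
    "make_mutation_set",
    "make_toy_structure",
    "degrade_protein",
    "write_structure_pdb",
    "write_fixture_bundle",
    "DEFAULT_VARIANT_REQUESTS",
    "DEFAULT_PSEUDOGENE_SPECS",
]

_NON_STOP_CODONS = sorted(
    c for c in STANDARD_CODE.table if c not in STANDARD_CODE.stop_codons
)
_AA_TO_CODON = {}
for _codon in sorted(STANDARD_CODE.table):
    _aa = STANDARD_CODE.table[_codon]
    _AA_TO_CODON.setdefault(_aa, _codon)
_CANONICAL_AA = sorted(set(STANDARD_CODE.table.values()) - {"*"})

# Substream offsets: one per generator, fixed forever.
_STREAM_TRANSCRIPT = 1
_STREAM_VARIANTS = 2
_STREAM_STRUCTURE = 3
_STREAM_PSEUDOGENE = 4


def _rng(seed: int, stream: int) -> random.Random:
    return random.Random(seed * 1000003 + stream)


# ---------------------------------------------------------------------------
# Transcript


def make_toy_transcript(
    seed: int,
    n_exons: int = 6,
    cds_len_codons: int = 145,
    allow_single_exon: bool = False,
) -> tuple[TranscriptModel, dict]:
    """Random multi-exon transcript with a clean CDS and known layout.

    The CDS codes ``cds_len_codons`` amino acids (ATG first, then non-stop
    codons, then a TAA stop); UTRs are at least 30 nt.  The last exon-exon
    junction is placed inside the CDS, far enough from both CDS ends that
    NMD-triggering and NMD-escaping premature stops are both constructible.
    """
    if n_exons < 2 and not allow_single_exon:
        raise ValueError("need >= 2 exons for the junction rule (allow_single_exon to override)")
    if cds_len_codons < 20:
        raise ValueError("CDS too short to place variants")
    rng = _rng(seed, _STREAM_TRANSCRIPT)
    utr5 = 30 + rng.randrange(0, 21)
    utr3 = 30 + rng.randrange(0, 41)
    body = "".join(rng.choice(_NON_STOP_CODONS) for _ in range(cds_len_codons - 1))
    cds = "ATG" + body + "TAA"
    utr5_seq = "".join(rng.choice("ACGT") for _ in range(utr5))
    # keep the 3' UTR free of early in-frame stops so frameshift translation
    # runs a controllable distance before stopping
    utr3_seq = "".join(rng.choice(_NON_STOP_CODONS) for _ in range(utr3 // 3)) + "TAA"
    cdna = utr5_seq + cds + utr3_seq
    n = len(cdna)
    cds_start = utr5 + 1
    cds_end = utr5 + len(cds)

    if n_exons == 1:
        exons = [(1, n)]
    else:
        last_junction = rng.randrange(cds_start + 150, cds_end - 60)
        if n_exons > 2:
            inner = sorted(rng.sample(range(20, last_junction - 10), n_exons - 2))
        else:
            inner = []
        cuts = inner + [last_junction]
        bounds = [0] + cuts + [n]
        exons = [(bounds[i] + 1, bounds[i + 1]) for i in range(len(bounds) - 1)]

    model = TranscriptModel(
        id=f"toy_tx_seed{seed}",
        cdna=Sequence(f"toy_tx_seed{seed}", cdna),
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
    )
    truth = {
        "cds_start": cds_start,
        "cds_end": cds_end,
        "protein_length": cds_len_codons,
        "exons": exons,
        "last_junction": model.junctions[-1] if model.junctions else None,
    }
    return model, truth


# ---------------------------------------------------------------------------
# Variants

#: default cohort: 64 variants, 30 NMD- / 19 NMD+ / 15 not-applicable
DEFAULT_VARIANT_REQUESTS: list[tuple[str, str, int]] = [
    ("MISSENSE", "NMD_MINUS", 20),
    ("SYNONYMOUS", "NMD_MINUS", 2),
    ("NONSENSE", "NMD_PLUS", 10),
    ("NONSENSE", "NMD_MINUS", 2),
    ("FRAMESHIFT", "NMD_PLUS", 9),
    ("FRAMESHIFT", "NMD_MINUS", 2),
    ("INFRAME_DEL", "NMD_MINUS", 2),
    ("INFRAME_INS", "NMD_MINUS", 2),
    ("START_LOSS", "NOT_APPLICABLE", 1),
    ("STOP_LOSS", "NOT_APPLICABLE", 1),
    ("SPLICE", "NOT_APPLICABLE", 13),
]


def _candidate_hgvs(klass: str, model: TranscriptModel, rng: random.Random) -> str:
    """Draw one candidate HGVS string aimed at the requested class."""
    cds = model.cds
    L = len(cds)
    n_aa = L // 3 - 1
    if klass == "MISSENSE" or klass == "SYNONYMOUS" or klass == "NONSENSE":
        codon_i = rng.randrange(1, n_aa)  # 0-based, skip initiator
        within = rng.randrange(3)
        c_pos = 3 * codon_i + within + 1
        ref = cds[c_pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        return f"c.{c_pos}{ref}>{alt}"
    if klass == "FRAMESHIFT":
        c_pos = rng.randrange(4, L - 3)
        if rng.random() < 0.5:
            return f"c.{c_pos}del"
        return f"c.{c_pos}dup"
    if klass == "INFRAME_DEL":
        span = 3 * rng.randrange(1, 4)
        c_start = rng.randrange(4, L - 3 - span)
        return f"c.{c_start}_{c_start + span - 1}del"
    if klass == "INFRAME_INS":
        c_pos = rng.randrange(4, L - 3)
        ins = "".join(rng.choice("ACGT") for _ in range(3 * rng.randrange(1, 3)))
        return f"c.{c_pos}_{c_pos + 1}ins{ins}"
    if klass == "START_LOSS":
        c_pos = rng.randrange(1, 4)
        ref = cds[c_pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        return f"c.{c_pos}{ref}>{alt}"
    if klass == "STOP_LOSS":
        c_pos = L - 2 + rng.randrange(3)
        ref = cds[c_pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        return f"c.{c_pos}{ref}>{alt}"
    if klass == "SPLICE":
        cds_junctions = [
            j - model.cds_start + 1
            for j in model.junctions
            if model.cds_start <= j <= model.cds_end - 3
        ]
        c_pos = rng.choice(cds_junctions)
        offset = rng.randrange(1, 6)
        return f"c.{c_pos}+{offset}G>A"
    raise ValueError(f"unknown requested class {klass!r}")


def make_mutation_set(
    model: TranscriptModel,
    requests: list[tuple[str, str, int]] | None = None,
    seed: int = 1,
    threshold_nt: int = 50,
    max_tries: int = 20000,
) -> tuple[pd.DataFrame, dict]:
    """Sample HGVS variants whose recomputed consequence and NMD category
    match the request, by rejection against the real classifiers.

    Returns a variant table (variant_id, hgvs_c, true_klass, true_nmd) and a
    ground-truth dict with planted class/category counts.
    """
    requests = DEFAULT_VARIANT_REQUESTS if requests is None else requests
    rng = _rng(seed, _STREAM_VARIANTS)
    rows: list[dict] = []
    used: set[str] = set()
    for klass, category, count in requests:
        produced = 0
        tries = 0
        while produced < count:
            tries += 1
            if tries > max_tries:
                raise RuntimeError(
                    f"could not satisfy request {klass}/{category} "
                    f"on transcript {model.id}"
                )
            hgvs = _candidate_hgvs(klass, model, rng)
            if hgvs in used:
                continue
            if klass == "SPLICE":
                try:
                    parse_hgvs_c(hgvs)
                except IntronicVariantError:
                    pass  # expected: routed to NOT_APPLICABLE downstream
                else:  # pragma: no cover
                    continue
                got_klass, got_cat = "SPLICE", "NOT_APPLICABLE"
            else:
                try:
                    v = parse_hgvs_c(hgvs)
                    cons = predict_consequence(model, v)
                except ValueError:
                    continue
                call = classify_nmd(model, cons, threshold_nt=threshold_nt)
                got_klass, got_cat = cons.klass.value, call.category.value
            if got_klass != klass or got_cat != category:
                continue
            used.add(hgvs)
            produced += 1
            rows.append(
                {
                    "variant_id": f"v{len(rows) + 1:03d}",
                    "hgvs_c": hgvs,
                    "true_klass": klass,
                    "true_nmd": category,
                }
            )
    table = pd.DataFrame(rows)
    klass_counts: dict[str, int] = {}
    cat_counts: dict[str, int] = {}
    for row in rows:
        klass_counts[row["true_klass"]] = klass_counts.get(row["true_klass"], 0) + 1
        cat_counts[row["true_nmd"]] = cat_counts.get(row["true_nmd"], 0) + 1
    total = len(rows)
    truth = {
        "n_variants": total,
        "class_counts": klass_counts,
        "nmd_counts": cat_counts,
        "nmd_fractions_pct": {
            k: 100.0 * v / total for k, v in sorted(cat_counts.items())
        },
        "threshold_nt": threshold_nt,
    }
    return table, truth


# ---------------------------------------------------------------------------
# Structures


@dataclass(frozen=True)
class PlantedContact:
    """A cluster of ``n_query_atoms`` x ``n_partner_atoms`` interchain atom
    pairs at ~``distance`` A between one protein and one RNA residue."""

    protein_res: int
    rna_res: int
    n_query_atoms: int
    n_partner_atoms: int
    distance: float = 3.4


@dataclass(frozen=True)
class PlantedHBond:
    """``n_bonds`` isolated N...O donor-acceptor pairs at ``distance`` A."""

    protein_res: int
    rna_res: int
    n_bonds: int
    distance: float = 2.9


@dataclass
class ToyStructureSpec:
    n_protein_res: int = 130
    n_rna_res: int = 60
    rna_start_res: int = 1500  # author numbering of the first RNA residue
    planted_contacts: list[PlantedContact] = field(default_factory=list)
    planted_hbonds: list[PlantedHBond] = field(default_factory=list)
    factor_chain: bool = True


def _r3(x: float, y: float, z: float) -> tuple[float, float, float]:
    # 3 decimals: the PDB fixed-format precision, so PDB and mmCIF renderings
    # of a fixture carry identical coordinates
    return (round(x, 3), round(y, 3), round(z, 3))


def make_toy_structure(
    seed: int,
    state_label: str,
    spec: ToyStructureSpec,
    cutoff: float = 4.0,
) -> tuple[StructureModel, dict]:
    """Two-chain (protein A / RNA B) toy structure with planted geometry.

    Backbones are laid out on well-separated lines (> cutoff + 1 A apart);
    planted contact clusters and H-bond pairs are attached near the involved
    protein residue.  Ground truth counts are recomputed from the final
    coordinates by an all-pairs scan, so they are exact by construction.
    """
    rng = _rng(seed, _STREAM_STRUCTURE) if seed is not None else random.Random(0)
    atoms: list[AtomRecord] = []
    # protein backbone: CA along x at y=0, plus a CB pseudo-atom
    for i in range(1, spec.n_protein_res + 1):
        x = 8.0 * i + rng.uniform(-0.3, 0.3)
        atoms.append(AtomRecord("A", i, "ALA", "CA", "C", _r3(x, 0.0, 0.0)))
        atoms.append(AtomRecord("A", i, "ALA", "CB", "C", _r3(x, 1.5, 0.2)))
    # RNA backbone: P and C1' along x at y=60
    for k in range(spec.n_rna_res):
        res = spec.rna_start_res + k
        x = 8.0 * k + rng.uniform(-0.3, 0.3)
        atoms.append(AtomRecord("B", res, "U", "P", "P", _r3(x, 60.0, 0.0)))
        atoms.append(AtomRecord("B", res, "U", "C1'", "C", _r3(x, 61.5, 0.3)))

    # planted contact clusters near the protein residue, z-offset +6
    counters: dict[tuple[str, int, str], int] = {}

    def _next_name(chain: str, res: int, prefix: str) -> str:
        key = (chain, res, prefix)
        counters[key] = counters.get(key, 0) + 1
        return f"{prefix}{counters[key]}"

    z_slot = 0
    for pc in spec.planted_contacts:
        z_slot += 1
        base = (8.0 * pc.protein_res, 0.0, 8.0 * z_slot)
        partner_base = (base[0], base[1] + pc.distance, base[2])
        for _ in range(pc.n_query_atoms):
            jitter = (rng.uniform(-0.2, 0.2), rng.uniform(-0.1, 0.1), rng.uniform(-0.2, 0.2))
            atoms.append(
                AtomRecord(
                    "A",
                    pc.protein_res,
                    "ALA",
                    _next_name("A", pc.protein_res, "C"),
                    "C",
                    _r3(base[0] + jitter[0], base[1] + jitter[1], base[2] + jitter[2]),
                )
            )
        for _ in range(pc.n_partner_atoms):
            jitter = (rng.uniform(-0.2, 0.2), rng.uniform(-0.1, 0.1), rng.uniform(-0.2, 0.2))
            atoms.append(
                AtomRecord(
                    "B",
                    pc.rna_res,
                    "U",
                    _next_name("B", pc.rna_res, "C"),
                    "C",
                    _r3(
                        partner_base[0] + jitter[0],
                        partner_base[1] + jitter[1],
                        partner_base[2] + jitter[2],
                    ),
                )
            )
    # planted H-bond pairs: isolated N...O pairs spaced 8 A apart, z-offset -8
    z_slot = 0
    for ph in spec.planted_hbonds:
        z_slot += 1
        for b in range(ph.n_bonds):
            x = 8.0 * ph.protein_res + 8.0 * b
            z = -8.0 * z_slot
            atoms.append(
                AtomRecord(
                    "A", ph.protein_res, "ALA",
                    _next_name("A", ph.protein_res, "N"), "N", _r3(x, 0.0, z),
                )
            )
            atoms.append(
                AtomRecord(
                    "B", ph.rna_res, "U",
                    _next_name("B", ph.rna_res, "O"), "O",
                    _r3(x, ph.distance, z),
                )
            )
    if spec.factor_chain:
        for i in range(1, 6):
            atoms.append(
                AtomRecord("F", i, "GLY", "CA", "C", _r3(8.0 * i, -120.0, 0.0))
            )

    model = StructureModel(state_label, atoms)

    # brute-force ground truth from the final coordinates
    from .structcontact import find_contacts, find_hbonds

    contacts = find_contacts(model, "A", cutoff=cutoff)
    contact_counts: dict[int, int] = {}
    for c in contacts:
        contact_counts[c.query_res] = contact_counts.get(c.query_res, 0) + 1
    hbonds = find_hbonds(model, "A")
    hbond_counts: dict[int, int] = {}
    for h in hbonds:
        hbond_counts[h.donor_res] = hbond_counts.get(h.donor_res, 0) + 1
    truth = {
        "state": state_label,
        "contact_counts": {str(k): v for k, v in sorted(contact_counts.items())},
        "hbond_counts": {str(k): v for k, v in sorted(hbond_counts.items())},
        "factor_chain": spec.factor_chain,
        "chain_roles": {"A": "ribosomal", "B": "ribosomal", "F": "factor"},
    }
    return model, truth


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.state_label
    gm = gemmi.Model("1")
    by_chain: dict[str, gemmi.Chain] = {}
    for a in model.atoms:
        if a.chain_id not in by_chain:
            by_chain[a.chain_id] = gemmi.Chain(a.chain_id)
        chain = by_chain[a.chain_id]
        if len(chain) == 0 or chain[len(chain) - 1].seqid.num != a.res_seq:
            res = gemmi.Residue()
            res.name = a.res_name
            res.seqid = gemmi.SeqId(a.res_seq, " ")
            chain.add_residue(res)
        res = chain[len(chain) - 1]
        atom = gemmi.Atom()
        atom.name = a.atom_name
        atom.element = gemmi.Element(a.element.capitalize())
        atom.pos = gemmi.Position(*a.xyz)
        atom.occ = 1.0
        res.add_atom(atom)
    for chain in by_chain.values():
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_structure_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel to legacy PDB via gemmi."""
    _to_gemmi(model).write_pdb(str(path))


def write_structure_cif(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel to mmCIF via gemmi."""
    _to_gemmi(model).make_mmcif_document().write_file(str(path))


#: default pseudo-assembly states; residue 62 is the contact hotspot analog
#: (45 pairs to two RNA residues in state B), 114-116 the loop analog where
#: only 115 ever reaches a neighbor.
def default_structure_specs() -> dict[str, ToyStructureSpec]:
    return {
        "A": ToyStructureSpec(
            planted_contacts=[
                PlantedContact(62, 1542, 4, 3),  # 12 pairs
                PlantedContact(25, 1510, 2, 2),  # 4 pairs
            ],
            planted_hbonds=[PlantedHBond(30, 1500, 3)],
        ),
        "B": ToyStructureSpec(
            planted_contacts=[
                PlantedContact(62, 1542, 9, 3),  # 27 pairs
                PlantedContact(62, 1543, 9, 2),  # 18 pairs -> 45 total for res 62
                PlantedContact(25, 1510, 2, 2),
            ],
            planted_hbonds=[PlantedHBond(30, 1500, 3)],
        ),
        "C": ToyStructureSpec(
            planted_contacts=[
                PlantedContact(62, 1542, 4, 2),  # 8 pairs
                PlantedContact(115, 1550, 1, 2),  # loop residue, 2 pairs
            ],
            planted_hbonds=[PlantedHBond(30, 1500, 3)],
        ),
    }


# ---------------------------------------------------------------------------
# Pseudogenes


def degrade_protein(
    reference: Sequence | str,
    target_identity: float,
    allow_indels: bool = False,
    seed: int = 1,
    frame_shift: int = 0,
    reverse: bool = False,
    name: str = "pseudo",
) -> tuple[Sequence, Sequence, dict]:
    """Degrade a protein to a target identity and back-translate it.

    Substitutes round((1 - target) * L) positions with different residues;
    with ``allow_indels``, additionally applies short (1-3 aa) insertions or
    deletions.  Back-translation uses a fixed codon per amino acid;
    ``frame_shift`` prepends that many nucleotides and ``reverse`` stores the
    reverse complement, to exercise frame selection.
    """
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must be in (0, 1]")
    ref = reference.residues if isinstance(reference, Sequence) else str(reference)
    rng = _rng(seed, _STREAM_PSEUDOGENE)
    L = len(ref)
    n_sub = round((1.0 - target_identity) * L)
    positions = sorted(rng.sample(range(L), n_sub))
    residues = list(ref)
    for p in positions:
        residues[p] = rng.choice([aa for aa in _CANONICAL_AA if aa != ref[p]])
    n_indels = 0
    if allow_indels:
        n_indels = max(1, round(L * (1.0 - target_identity) / 8))
        for _ in range(n_indels):
            at = rng.randrange(1, len(residues) - 1)
            size = rng.randrange(1, 4)
            if rng.random() < 0.5 and len(residues) > size + 10:
                del residues[at : at + size]
            else:
                residues[at:at] = [rng.choice(_CANONICAL_AA) for _ in range(size)]
    protein = "".join(residues)
    dna = "G" * frame_shift + "".join(_AA_TO_CODON[aa] for aa in protein)
    if reverse:
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        dna = "".join(comp[b] for b in reversed(dna))
    expected_frame = -(1) if reverse else frame_shift + 1
    truth = {
        "id": name,
        "target_identity_pct": 100.0 * target_identity,
        "n_substitutions": n_sub,
        "n_indel_events": n_indels,
        "expected_frame": expected_frame,
        "planted_protein_length": len(protein),
        "tight_identity": not allow_indels,
        # heavily degraded sequences can legitimately score best in another
        # frame; the planted frame is only a guarantee when most residues
        # survive degradation intact
        "frame_reliable": target_identity >= 0.75,
    }
    return (
        Sequence(name + "_protein", protein, "PROTEIN"),
        Sequence(name, dna, "DNA"),
        truth,
    )


#: identity ladder mirroring the published pseudogene family profile;
#: the P3 analog (0.904, no indels) is the near-intact member.
DEFAULT_PSEUDOGENE_SPECS: list[tuple[str, float, bool, int, bool]] = [
    # (name, target identity, allow_indels, frame_shift, reverse)
    ("PSEUDO1", 0.51, True, 0, False),
    ("PSEUDO2", 0.415, True, 0, False),
    ("PSEUDO3", 0.904, False, 1, False),
    ("PSEUDO4", 0.314, True, 0, False),
    ("PSEUDO5", 0.247, True, 2, False),
    ("PSEUDO6", 0.206, True, 0, False),
    ("PSEUDO7", 0.117, True, 0, True),
]


# ---------------------------------------------------------------------------
# Bundle


@dataclass
class FixtureBundle:
    outdir: Path
    seed: int
    transcript: TranscriptModel
    variants: pd.DataFrame
    structures: dict[str, StructureModel]
    ground_truth: dict


def write_fixture_bundle(
    outdir: str | Path,
    seed: int = 1,
    n_exons: int = 6,
    cds_len_codons: int = 145,
    variant_requests: list[tuple[str, str, int]] | None = None,
    structure_specs: dict[str, ToyStructureSpec] | None = None,
    pseudogene_specs: list[tuple[str, float, bool, int, bool]] | None = None,
) -> FixtureBundle:
    """Generate and write the full fixture bundle for one seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    model, tx_truth = make_toy_transcript(seed, n_exons, cds_len_codons)
    write_fasta([model.cdna], outdir / "transcript.fa")
    pd.DataFrame(
        [
            {"exon_index": i + 1, "start": s, "end": e}
            for i, (s, e) in enumerate(model.exons)
        ]
    ).to_csv(outdir / "exons.tsv", sep="\t", index=False)

    variants, var_truth = make_mutation_set(model, variant_requests, seed)
    variants.to_csv(outdir / "variants.tsv", sep="\t", index=False)

    specs = structure_specs or default_structure_specs()
    structures: dict[str, StructureModel] = {}
    struct_truth: dict[str, dict] = {}
    for state, spec in sorted(specs.items()):
        st_model, st_truth = make_toy_structure(seed, state, spec)
        structures[state] = st_model
        struct_truth[state] = st_truth
        write_structure_pdb(st_model, outdir / f"state_{state}.pdb")
    # one state also rendered as mmCIF to exercise that read path
    first_state = sorted(specs)[0]
    write_structure_cif(structures[first_state], outdir / f"state_{first_state}.cif")

    from .genemodel import translate_cds

    wt_protein, _ = translate_cds(model.cds)
    write_fasta(
        [Sequence("reference_protein", wt_protein, "PROTEIN")],
        outdir / "reference_protein.fa",
    )
    pg_specs = DEFAULT_PSEUDOGENE_SPECS if pseudogene_specs is None else pseudogene_specs
    pg_seqs: list[Sequence] = []
    pg_truth: list[dict] = []
    for i, (name, ident, indels, shift, rev) in enumerate(pg_specs):
        _, dna, truth = degrade_protein(
            wt_protein, ident, indels, seed + 7919 * (i + 1), shift, rev, name
        )
        pg_seqs.append(dna)
        pg_truth.append(truth)
    write_fasta(pg_seqs, outdir / "pseudogenes.fa")

    # a ready-to-run pipeline config pointing at the bundle's own files
    config = {
        "outdir": "ribovar_out",
        "transcript_fasta": "transcript.fa",
        "exon_table": "exons.tsv",
        "cds_start": model.cds_start,
        "cds_end": model.cds_end,
        "variants": "variants.tsv",
        "structures": {state: f"state_{state}.pdb" for state in sorted(specs)},
        "query_chain": "A",
        "chain_roles": {"A": "ribosomal", "B": "ribosomal", "F": "factor"},
        "pseudogenes": "pseudogenes.fa",
        "reference_protein": "reference_protein.fa",
    }
    import yaml

    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    ground_truth = {
        "seed": seed,
        "transcript": tx_truth,
        "variants": var_truth,
        "structures": struct_truth,
        "pseudogenes": pg_truth,
        "wild_type_protein": wt_protein,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(ground_truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return FixtureBundle(outdir, seed, model, variants, structures, ground_truth)
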