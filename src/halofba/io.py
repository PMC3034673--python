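"""Model serialization: reaction-equation strings, TSV tables, JSON, workbooks.

The native dialect is a pair of TSV tables:

``reactions.tsv``
    columns ``id, name, equation, reversible (0/1, optional), lower_bound,
    upper_bound, ec_numbers (";"-separated), genes (boolean expression),
    subsystem, kind``.  ``reversible`` is inferred from the equation arrow
    when absent.

``metabolites.tsv``
    columns ``id, name, compartment, formula, charge``.

``model.json`` mirrors :class:`~halofba.model.MetabolicModel` with a
mandatory ``schema_version``.  A supplementary spreadsheet workbook is
ingested by :func:`convert_workbook`, which locates the reaction and
metabolite sheets by their column headers (case-insensitive, with synonyms)
and emits the two TSVs plus a column-mapping log for manual confirmation.
"""

from __future__ import annotations

import json
import math
import re
from fractions import Fraction
from pathlib import Path

import pandas as pd

from halofba.errors import EquationParseError, LoadError, SchemaVersionError
from halofba.model import MetabolicModel, Metabolite, Reaction

SCHEMA_VERSION = "1.0"

_ARROWS = {"->": False, "=>": False, "-->": False, "<=>": True, "<->": True, "<==>": True}
_SPECIES = re.compile(r"^(?P<id>[^\s\[\]]+)\[(?P<comp>[A-Za-z0-9]+)\]$")
_NUMBER = re.compile(r"^\(?(\d+(\.\d+)?([eE][+-]?\d+)?|\d+/\d+|\.\d+)\)?$")


# --------------------------------------------------------------------------
# reaction equation strings
# --------------------------------------------------------------------------
def _parse_coefficient(token: str) -> float:
    token = token.strip("()")
    if "/" in token:
        return float(Fraction(token))
    return float(token)


def parse_reaction_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse ``"2 a[c] + b[c] -> c[c]"`` into a stoichiometry map and a
    reversibility flag.

    Left-hand species get negative coefficients.  ``->`` marks an
    irreversible reaction, ``<=>`` a reversible one.  Either side may be
    empty (exchange reactions).  Errors carry the column offset of the
    offending token.
    """
    tokens = [(m.group(0), m.start()) for m in re.finditer(r"\S+", text)]
    arrow_positions = [i for i, (tok, _) in enumerate(tokens) if tok in _ARROWS]
    if not arrow_positions:
        raise EquationParseError("no reaction arrow ('->' or '<=>') found", column=0)
    if len(arrow_positions) > 1:
        raise EquationParseError("multiple reaction arrows", column=tokens[arrow_positions[1]][1])
    ai = arrow_positions[0]
    reversible = _ARROWS[tokens[ai][0]]

    def parse_side(side_tokens, sign: float) -> dict[str, float]:
        out: dict[str, float] = {}
        coeff: float | None = None
        expect_species = True
        for tok, col in side_tokens:
            if tok == "+":
                if expect_species:
                    raise EquationParseError("dangling '+'", column=col)
                expect_species = True
                continue
            if not expect_species:
                raise EquationParseError(f"expected '+' before {tok!r}", column=col)
            if _NUMBER.match(tok) and coeff is None:
                coeff = _parse_coefficient(tok)
                continue
            m = _SPECIES.match(tok)
            if not m:
                raise EquationParseError(
                    f"malformed species token {tok!r} (compartment tag like '[c]' required)",
                    column=col,
                )
            comp = m.group("comp")
            species = f"{m.group('id')}[{comp}]"
            if species in out:
                raise EquationParseError(f"duplicate species {species!r} on one side", column=col)
            c = coeff if coeff is not None else 1.0
            if c == 0:
                raise EquationParseError(f"zero coefficient for {species!r}", column=col)
            out[species] = sign * c
            coeff = None
            expect_species = False
        if coeff is not None:
            raise EquationParseError("dangling coefficient at end of side", column=side_tokens[-1][1])
        if expect_species and side_tokens:
            raise EquationParseError("trailing '+'", column=side_tokens[-1][1])
        return out

    left = parse_side(tokens[:ai], -1.0)
    right = parse_side(tokens[ai + 1 :], +1.0)
    stoich = dict(left)
    for species, coeff in right.items():
        net = stoich.get(species, 0.0) + coeff
        if abs(net) < 1e-12:
            del stoich[species]
        else:
            stoich[species] = net
    if not stoich:
        raise EquationParseError("equation has empty (or fully cancelling) stoichiometry", column=0)
    return stoich, reversible


def _format_coeff(c: float) -> str:
    if c == int(c):
        return str(int(c))
    frac = Fraction(c).limit_denominator(10**6)
    if abs(float(frac) - c) < 1e-12 and frac.denominator <= 1000:
        return f"{frac.numerator}/{frac.denominator}"
    return repr(c)


def format_reaction_equation(stoichiometry: dict[str, float], reversible: bool) -> str:
    """Inverse of :func:`parse_reaction_equation` (species keep map order)."""
    left, right = [], []
    for species, coeff in stoichiometry.items():
        target = left if coeff < 0 else right
        mag = abs(coeff)
        target.append(species if mag == 1 else f"{_format_coeff(mag)} {species}")
    arrow = "<=>" if reversible else "->"
    return f"{' + '.join(left)} {arrow} {' + '.join(right)}".strip()


# --------------------------------------------------------------------------
# table ingestion
# --------------------------------------------------------------------------
#: case-insensitive header synonyms for the two tables
REACTION_COLUMN_SYNONYMS = {
    "id": {"id", "reaction id", "reaction_id", "rxn", "rxn id", "rxn_id", "abbreviation", "reaction abbreviation"},
    "name": {"name", "reaction name", "reaction", "description"},
    "equation": {"equation", "reaction equation", "formula", "reaction formula", "stoichiometry"},
    "reversible": {"reversible", "reversibility", "rev"},
    "lower_bound": {"lower_bound", "lower bound", "lb", "alpha"},
    "upper_bound": {"upper_bound", "upper bound", "ub", "beta"},
    "ec_numbers": {"ec_numbers", "ec number", "ec numbers", "ec", "ec-number"},
    "genes": {"genes", "gene", "gene association", "gene_association", "gpr", "gene-reaction association", "locus tags"},
    "subsystem": {"subsystem", "pathway", "category", "functional category"},
    "kind": {"kind", "type", "reaction type"},
}
METABOLITE_COLUMN_SYNONYMS = {
    "id": {"id", "metabolite id", "metabolite_id", "met", "met id", "met_id", "abbreviation", "metabolite abbreviation"},
    "name": {"name", "metabolite name", "metabolite", "description"},
    "compartment": {"compartment", "comp", "location"},
    "formula": {"formula", "chemical formula", "elemental formula", "composition"},
    "charge": {"charge", "net charge"},
}


def _map_columns(columns, synonyms) -> dict[str, str]:
    """Map canonical field -> actual column name, matching case-insensitively."""
    lowered = {str(c).strip().lower(): c for c in columns}
    mapping = {}
    for field_name, alts in synonyms.items():
        for alt in alts:
            if alt in lowered:
                mapping[field_name] = lowered[alt]
                break
    return mapping


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and not value.strip()


def _cell(row, mapping, field_name, default=None):
    col = mapping.get(field_name)
    if col is None:
        return default
    value = row[col]
    return default if _is_missing(value) else value


def infer_reaction_kind(stoich: dict[str, float], compartment_of: dict[str, str], name: str = "") -> str:
    """Heuristic kind assignment for tables lacking an explicit column."""
    if "biomass" in name.lower():
        return "biomass"
    comps = {compartment_of.get(m, "c") for m in stoich}
    if comps == {"e"}:
        return "exchange"
    if len(comps) > 1:
        return "transport"
    return "enzymatic"


def read_model_tables(
    reaction_table: pd.DataFrame,
    metabolite_table: pd.DataFrame,
    model_id: str = "model",
    objective_id: str | None = None,
) -> MetabolicModel:
    """Build a model from reaction/metabolite DataFrames in the TSV dialect.

    All offending rows are collected into a single :class:`LoadError` rather
    than failing on the first.
    """
    problems: list[str] = []
    rmap = _map_columns(reaction_table.columns, REACTION_COLUMN_SYNONYMS)
    mmap = _map_columns(metabolite_table.columns, METABOLITE_COLUMN_SYNONYMS)
    for required, mapping, which in (
        ("id", rmap, "reactions"),
        ("equation", rmap, "reactions"),
        ("id", mmap, "metabolites"),
        ("compartment", mmap, "metabolites"),
    ):
        if required not in mapping:
            problems.append(f"{which} table: missing mandatory column {required!r}")
    if problems:
        raise LoadError(problems)

    metabolites: list[Metabolite] = []
    seen_mets: set[str] = set()
    known_fields = {mmap.get(k) for k in METABOLITE_COLUMN_SYNONYMS}
    for i, row in metabolite_table.iterrows():
        mid = str(_cell(row, mmap, "id", "")).strip()
        if not mid:
            problems.append(f"metabolites row {i}: empty id")
            continue
        if mid in seen_mets:
            problems.append(f"metabolites row {i}: duplicate id {mid!r}")
            continue
        seen_mets.add(mid)
        charge = _cell(row, mmap, "charge")
        formula = _cell(row, mmap, "formula")
        annotations = {
            str(c): row[c] for c in metabolite_table.columns if c not in known_fields and not _is_missing(row[c])
        }
        metabolites.append(
            Metabolite(
                id=mid,
                name=str(_cell(row, mmap, "name", "")),
                compartment=str(_cell(row, mmap, "compartment", "c")).strip(),
                formula=None if formula is None else str(formula).strip(),
                charge=None if charge is None else int(float(charge)),
                annotations=annotations,
            )
        )
    compartment_of = {m.id: m.compartment for m in metabolites}

    reactions: list[Reaction] = []
    seen_rxns: set[str] = set()
    known_fields = {rmap.get(k) for k in REACTION_COLUMN_SYNONYMS}
    for i, row in reaction_table.iterrows():
        rid = str(_cell(row, rmap, "id", "")).strip()
        if not rid:
            problems.append(f"reactions row {i}: empty id")
            continue
        if rid in seen_rxns:
            problems.append(f"reactions row {i}: duplicate id {rid!r}")
            continue
        seen_rxns.add(rid)
        equation = str(_cell(row, rmap, "equation", ""))
        try:
            stoich, arrow_reversible = parse_reaction_equation(equation)
        except EquationParseError as exc:
            problems.append(f"reactions row {i} ({rid}): {exc}")
            continue
        dangling = sorted(m for m in stoich if m not in seen_mets)
        if dangling:
            problems.append(f"reactions row {i} ({rid}): undeclared metabolites {dangling}")
            continue
        rev_cell = _cell(row, rmap, "reversible")
        reversible = arrow_reversible if rev_cell is None else bool(int(float(rev_cell)))
        lb = _cell(row, rmap, "lower_bound")
        ub = _cell(row, rmap, "upper_bound")
        ec_raw = _cell(row, rmap, "ec_numbers", "")
        name = str(_cell(row, rmap, "name", ""))
        kind = _cell(row, rmap, "kind")
        annotations = {
            str(c): row[c] for c in reaction_table.columns if c not in known_fields and not _is_missing(row[c])
        }
        reactions.append(
            Reaction(
                id=rid,
                name=name,
                stoichiometry=stoich,
                reversible=reversible,
                lower_bound=None if lb is None else float(lb),
                upper_bound=None if ub is None else float(ub),
                ec_numbers=[e.strip() for e in str(ec_raw).split(";") if e.strip()],
                gene_association=str(_cell(row, rmap, "genes", "")),
                subsystem=str(_cell(row, rmap, "subsystem", "")),
                kind=str(kind).strip() if kind is not None else infer_reaction_kind(stoich, compartment_of, name),
                annotations=annotations,
            )
        )
    if problems:
        raise LoadError(problems)

    genes = sorted(set().union(*(r.genes for r in reactions)) if reactions else set())
    if objective_id is None:
        biomass = [r.id for r in reactions if r.kind == "biomass"]
        objective_id = biomass[0] if biomass else None
    model = MetabolicModel(
        id=model_id, metabolites=metabolites, reactions=reactions, genes=genes, objective_id=objective_id
    )
    model.validate()
    return model


# --------------------------------------------------------------------------
# TSV round trip
# --------------------------------------------------------------------------
def model_to_tables(model: MetabolicModel) -> tuple[pd.DataFrame, pd.DataFrame]:
    rrows = []
    for r in model.reactions:
        rrows.append(
            {
                "id": r.id,
                "name": r.name,
                "equation": format_reaction_equation(r.stoichiometry, r.reversible),
                "reversible": int(r.reversible),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "ec_numbers": ";".join(r.ec_numbers),
                "genes": r.gene_association,
                "subsystem": r.subsystem,
                "kind": r.kind,
            }
        )
    mrows = []
    for m in model.metabolites:
        mrows.append(
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": "" if m.formula is None else m.formula,
                "charge": "" if m.charge is None else m.charge,
            }
        )
    return pd.DataFrame(rrows), pd.DataFrame(mrows)


def write_model_tsv(model: MetabolicModel, out_dir: str | Path) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rdf, mdf = model_to_tables(model)
    rpath, mpath = out_dir / "reactions.tsv", out_dir / "metabolites.tsv"
    rdf.to_csv(rpath, sep="\t", index=False)
    mdf.to_csv(mpath, sep="\t", index=False)
    return rpath, mpath


def read_model_tsv(
    reactions_path: str | Path,
    metabolites_path: str | Path | None = None,
    model_id: str | None = None,
    objective_id: str | None = None,
) -> MetabolicModel:
    """Load the dialect from files; ``reactions_path`` may be the directory."""
    rp = Path(reactions_path)
    if rp.is_dir():
        rp, metabolites_path = rp / "reactions.tsv", rp / "metabolites.tsv"
    if metabolites_path is None:
        metabolites_path = rp.with_name("metabolites.tsv")
    rdf = pd.read_csv(rp, sep="\t", dtype=str, keep_default_na=False).replace("", None)
    mdf = pd.read_csv(metabolites_path, sep="\t", dtype=str, keep_default_na=False).replace("", None)
    return read_model_tables(rdf, mdf, model_id=model_id or rp.parent.name, objective_id=objective_id)


# --------------------------------------------------------------------------
# JSON round trip
# --------------------------------------------------------------------------
def write_model_json(model: MetabolicModel, path: str | Path | None = None) -> dict:
    """Serialize to a JSON-compatible document (and file when ``path`` given)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "id": model.id,
        "objective_id": model.objective_id,
        "genes": list(model.genes),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "charge": m.charge,
                "annotations": m.annotations,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": r.stoichiometry,
                "reversible": r.reversible,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "ec_numbers": r.ec_numbers,
                "gene_association": r.gene_association,
                "subsystem": r.subsystem,
                "kind": r.kind,
                "annotations": r.annotations,
            }
            for r in model.reactions
        ],
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=1))
    return doc


def read_model_json(document: dict | str | Path) -> MetabolicModel:
    if not isinstance(document, dict):
        document = json.loads(Path(document).read_text())
    version = document.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaVersionError(f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION!r})")
    metabolites = [
        Metabolite(
            id=m["id"],
            name=m.get("name", ""),
            compartment=m.get("compartment", "c"),
            formula=m.get("formula"),
            charge=m.get("charge"),
            annotations=m.get("annotations", {}),
        )
        for m in document["metabolites"]
    ]
    reactions = [
        Reaction(
            id=r["id"],
            name=r.get("name", ""),
            stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
            reversible=r.get("reversible", False),
            lower_bound=r.get("lower_bound"),
            upper_bound=r.get("upper_bound"),
            ec_numbers=list(r.get("ec_numbers", [])),
            gene_association=r.get("gene_association", ""),
            subsystem=r.get("subsystem", ""),
            kind=r.get("kind", "enzymatic"),
            annotations=r.get("annotations", {}),
        )
        for r in document["reactions"]
    ]
    model = MetabolicModel(
        id=document.get("id", "model"),
        metabolites=metabolites,
        reactions=reactions,
        genes=list(document.get("genes", [])),
        objective_id=document.get("objective_id"),
    )
    model.validate()
    return model


def load_model(path: str | Path) -> MetabolicModel:
    """Load a model from a ``.json`` file or a TSV directory/file pair."""
    p = Path(path)
    if p.suffix == ".json":
        return read_model_json(p)
    return read_model_tsv(p)


# --------------------------------------------------------------------------
# workbook conversion
# --------------------------------------------------------------------------
def convert_workbook(workbook_path: str | Path, out_dir: str | Path) -> dict:
    """Convert a supplementary spreadsheet workbook to the TSV dialect.

    The sheet holding reactions (respectively metabolites) is located by
    matching its headers against the documented synonyms; the winning sheet
    is the one resolving the most canonical columns including the mandatory
    ones.  Returns (and writes to ``column_mapping.json``) the sheet/column
    mapping so a curator can confirm it.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sheets = pd.read_excel(workbook_path, sheet_name=None, engine="openpyxl")

    def best_sheet(synonyms, mandatory):
        scored = []
        for name, df in sheets.items():
            mapping = _map_columns(df.columns, synonyms)
            if all(k in mapping for k in mandatory):
                scored.append((len(mapping), name, mapping))
        if not scored:
            raise LoadError([f"no sheet provides mandatory columns {sorted(mandatory)}"])
        scored.sort(key=lambda t: (-t[0], t[1]))
        return scored[0][1], scored[0][2]

    rxn_sheet, rxn_map = best_sheet(REACTION_COLUMN_SYNONYMS, {"id", "equation"})
    met_sheet, met_map = best_sheet(METABOLITE_COLUMN_SYNONYMS, {"id", "compartment"})
    if met_sheet == rxn_sheet:
        raise LoadError(["reaction and metabolite tables resolved to the same sheet"])

    def normalized(df, mapping):
        renamed = df.rename(columns={v: k for k, v in mapping.items()})
        return renamed

    normalized(sheets[rxn_sheet], rxn_map).to_csv(out_dir / "reactions.tsv", sep="\t", index=False)
    normalized(sheets[met_sheet], met_map).to_csv(out_dir / "metabolites.tsv", sep="\t", index=False)
    log = {
        "workbook": str(workbook_path),
        "reactions_sheet": rxn_sheet,
        "reactions_columns": rxn_map,
        "metabolites_sheet": met_sheet,
        "metabolites_columns": met_map,
    }
    (out_dir / "column_mapping.json").write_text(json.dumps(log, indent=1))
    return log
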