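"""Parser for the BNGL-subset model text format.

The subset covers exactly what the bundled models need:

* ``begin parameters`` — ``symbol value`` pairs (numbers or expressions over
  previously defined symbols); optional, the integrin model keeps its
  parameter table in a separate TSV.
* ``begin compartments`` — ``name relative_volume``.
* ``begin molecule types`` — ``NAME(site~s1~s2,...) @C1,C2 [symmetric{a,b}]``.
* ``begin seed species`` — fully specified species pattern plus the symbol
  (or expression) giving its total amount.
* ``begin observables`` — ``name pattern [pattern ...]``; the observable value
  is the embedding-weighted sum over species.
* ``begin reaction rules`` — ``id: lhs -> rhs rate`` or
  ``id: lhs <-> rhs kf, kr``; the transformation (bond add/delete, one state
  change, or a compartment change) is inferred by diffing the two sides.

Anything outside the subset is rejected with a line-numbered error.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import sympy

from .engine import (
    BOUND,
    FREE,
    WILD,
    Action,
    MoleculeDef,
    Pattern,
    PatternMol,
    Rule,
    RuleDefinitionError,
    SiteDef,
    Species,
    make_species,
)

__all__ = ["ParseError", "ParsedModel", "SeedSpec", "ObservableDef", "parse_model", "parse_pattern"]


class ParseError(ValueError):
    def __init__(self, lineno: int, msg: str):
        super().__init__(f"line {lineno}: {msg}")
        self.lineno = lineno


@dataclass
class SeedSpec:
    species: Species
    amount_expr: str


@dataclass
class ObservableDef:
    name: str
    patterns: list[Pattern]


@dataclass
class RuleLine:
    """One rule as written (possibly reversible); expands to 1–2 engine Rules."""

    rule_id: str
    reversible: bool
    lhs: list[Pattern]
    rhs: list[Pattern]
    rate_forward: str
    rate_reverse: str | None
    lineno: int


@dataclass
class ParsedModel:
    molecules: dict[str, MoleculeDef] = field(default_factory=dict)
    compartments: dict[str, float] = field(default_factory=dict)
    parameters: dict[str, float] = field(default_factory=dict)
    seeds: list[SeedSpec] = field(default_factory=list)
    observables: list[ObservableDef] = field(default_factory=list)
    rule_lines: list[RuleLine] = field(default_factory=list)
    rules: list[Rule] = field(default_factory=list)


_SITE_RE = re.compile(
    r"^(?P<name>[A-Za-z_]\w*)"
    r"(?P<states>(~\w+)*)"
    r"(?P<bond>!(\d+|\+|\?))?$"
)
_MOL_RE = re.compile(r"^(?P<name>[A-Za-z_]\w*)\((?P<sites>[^()]*)\)$")


def _split_mols(text: str) -> list[str]:
    """Split 'A(x!1).B(y!1)' into molecule tokens."""
    out, depth, cur = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "." and depth == 0:
            out.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    if cur:
        out.append("".join(cur))
    return out


def parse_pattern(text: str, lineno: int = 0) -> Pattern:
    """Parse one complex pattern, e.g. ``TAL(ptb!1,act~A).INT(npxy~U!1)@PM``."""
    compartment = None
    if "@" in text:
        text, comp = text.rsplit("@", 1)
        compartment = comp.strip()
        if not compartment:
            raise ParseError(lineno, "empty compartment tag")
    mols = []
    for tok in _split_mols(text.strip()):
        m = _MOL_RE.match(tok.strip())
        if not m:
            raise ParseError(lineno, f"cannot parse molecule {tok!r}")
        sites = []
        body = m.group("sites").strip()
        if body:
            for stok in body.split(","):
                sm = _SITE_RE.match(stok.strip())
                if not sm:
                    raise ParseError(lineno, f"cannot parse site {stok!r}")
                states = [s for s in sm.group("states").split("~") if s]
                if len(states) > 1:
                    raise ParseError(lineno, f"site {stok!r}: one state allowed here")
                state = states[0] if states else None
                bond_tok = sm.group("bond")
                if bond_tok is None:
                    bond: object = FREE
                elif bond_tok == "!+":
                    bond = BOUND
                elif bond_tok == "!?":
                    bond = WILD
                else:
                    bond = int(bond_tok[1:])
                sites.append((sm.group("name"), (state, bond)))
        mols.append(PatternMol(name=m.group("name"), sites=tuple(sites)))
    return Pattern(mols=tuple(mols), compartment=compartment)


def _pattern_bonds(patterns: list[Pattern]) -> dict[tuple[int, int], list[tuple[int, int, str]]]:
    """Bond id -> endpoints as (pattern idx, mol idx, site), ids scoped per pattern."""
    bonds: dict[tuple[int, int], list[tuple[int, int, str]]] = {}
    for pi, pat in enumerate(patterns):
        for mi, pm in enumerate(pat.mols):
            for site, (_state, bond) in pm.sites:
                if isinstance(bond, int):
                    bonds.setdefault((pi, bond), []).append((pi, mi, site))
    return bonds


def _flatten(patterns: list[Pattern]) -> list[tuple[int, int, PatternMol]]:
    out = []
    for pi, pat in enumerate(patterns):
        for mi, pm in enumerate(pat.mols):
            out.append((pi, mi, pm))
    return out


def _infer_action(lhs: list[Pattern], rhs: list[Pattern], lineno: int) -> Action:
    """Diff the two sides of a rule; exactly one elementary change is allowed."""
    lflat, rflat = _flatten(lhs), _flatten(rhs)
    if [pm.name for _, _, pm in lflat] != [pm.name for _, _, pm in rflat]:
        raise ParseError(lineno, "molecule sequence differs between rule sides")

    changes: list[Action] = []

    # compartment change: single complex on both sides, both tagged, different
    # tags.  Tags elsewhere are matching constraints on the reactants only.
    if (
        len(lhs) == 1
        and len(rhs) == 1
        and lhs[0].compartment is not None
        and rhs[0].compartment is not None
        and lhs[0].compartment != rhs[0].compartment
    ):
        changes.append(
            Action(kind="compartment-change", new_compartment=rhs[0].compartment)
        )

    # state changes
    for k, (lref, rref) in enumerate(zip(lflat, rflat)):
        lpi, lmi, lpm = lref
        _, _, rpm = rref
        lmap, rmap = lpm.site_map(), rpm.site_map()
        if set(lmap) != set(rmap):
            raise ParseError(
                lineno, f"molecule {lpm.name}: sites listed differ between sides"
            )
        for site in lmap:
            ls, rs = lmap[site][0], rmap[site][0]
            if ls != rs:
                if rs is None:
                    raise ParseError(lineno, f"state of {lpm.name}.{site} erased on rhs")
                changes.append(
                    Action(kind="state-change", a=(lpi, lmi, site), new_state=rs)
                )

    # bond changes: compare bond endpoint sets (by flattened mol index + site)
    def endpoint_set(patterns: list[Pattern]) -> set[frozenset]:
        flat_index = {}
        k = 0
        for pi, pat in enumerate(patterns):
            for mi, _pm in enumerate(pat.mols):
                flat_index[(pi, mi)] = k
                k += 1
        out = set()
        for ends in _pattern_bonds(patterns).values():
            if len(ends) != 2:
                raise ParseError(lineno, "dangling bond id in rule")
            (p1, m1, s1), (p2, m2, s2) = ends
            out.add(
                frozenset({(flat_index[(p1, m1)], s1), (flat_index[(p2, m2)], s2)})
            )
        return out

    lbonds, rbonds = endpoint_set(lhs), endpoint_set(rhs)
    added = rbonds - lbonds
    removed = lbonds - rbonds

    def to_ref(flat_k: int, site: str, patterns: list[Pattern]) -> tuple[int, int, str]:
        k = 0
        for pi, pat in enumerate(patterns):
            for mi, _pm in enumerate(pat.mols):
                if k == flat_k:
                    return (pi, mi, site)
                k += 1
        raise AssertionError

    for bond in added:
        (k1, s1), (k2, s2) = sorted(bond)
        changes.append(
            Action(kind="bond-add", a=to_ref(k1, s1, lhs), b=to_ref(k2, s2, lhs))
        )
    for bond in removed:
        (k1, s1), _ = sorted(bond)
        changes.append(Action(kind="bond-delete", a=to_ref(k1, s1, lhs)))

    if len(changes) != 1:
        raise ParseError(
            lineno,
            f"rule must perform exactly one transformation, found {len(changes)}",
        )
    act = changes[0]
    if act.kind == "bond-add" and act.a is not None and act.b is not None:
        if act.a[0] == act.b[0] and len(lhs) == 1:
            raise ParseError(lineno, "intra-complex bond formation is not supported")
    return act


def _expand_rule_line(rl: RuleLine) -> list[Rule]:
    rules = [
        Rule(
            name=rl.rule_id,
            reactants=tuple(rl.lhs),
            action=_infer_action(rl.lhs, rl.rhs, rl.lineno),
            rate=rl.rate_forward,
        )
    ]
    if rl.reversible:
        assert rl.rate_reverse is not None
        rules.append(
            Rule(
                name=rl.rule_id + "_r",
                reactants=tuple(rl.rhs),
                action=_infer_action(rl.rhs, rl.lhs, rl.lineno),
                rate=rl.rate_reverse,
            )
        )
    return rules


def _eval_expr(expr: str, env: dict[str, float], lineno: int) -> float:
    try:
        val = sympy.sympify(expr, rational=False).subs(env)
        return float(val)
    except Exception as exc:
        raise ParseError(lineno, f"cannot evaluate {expr!r}: {exc}") from exc


def parse_model(text: str) -> ParsedModel:
    model = ParsedModel()
    block: str | None = None
    known_blocks = {
        "parameters",
        "compartments",
        "molecule types",
        "seed species",
        "observables",
        "reaction rules",
    }
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("begin "):
            name = line[6:].strip()
            if name not in known_blocks:
                raise ParseError(lineno, f"unknown block {name!r}")
            if block is not None:
                raise ParseError(lineno, f"nested block {name!r}")
            block = name
            continue
        if line.startswith("end "):
            name = line[4:].strip()
            if block != name:
                raise ParseError(lineno, f"mismatched end {name!r}")
            block = None
            continue
        if block is None:
            raise ParseError(lineno, f"statement outside any block: {line!r}")

        if block == "parameters":
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise ParseError(lineno, "expected: symbol value")
            model.parameters[parts[0]] = _eval_expr(parts[1], model.parameters, lineno)

        elif block == "compartments":
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(lineno, "expected: name relative_volume")
            model.compartments[parts[0]] = float(parts[1])

        elif block == "molecule types":
            m = re.match(
                r"^(?P<sig>[A-Za-z_]\w*\([^()]*\))"
                r"(\s*@(?P<comps>[\w,]+))?"
                r"(\s*symmetric\{(?P<sym>[\w,]+)\})?$",
                line,
            )
            if not m:
                raise ParseError(lineno, f"cannot parse molecule type {line!r}")
            sig = m.group("sig")
            name = sig.split("(", 1)[0]
            body = sig[len(name) + 1 : -1].strip()
            sites = []
            if body:
                for stok in body.split(","):
                    bits = stok.strip().split("~")
                    sites.append(SiteDef(name=bits[0], states=tuple(bits[1:])))
            comps = frozenset((m.group("comps") or "CP").split(","))
            sym = ()
            if m.group("sym"):
                sym = (frozenset(m.group("sym").split(",")),)
            if name in model.molecules:
                raise ParseError(lineno, f"duplicate molecule type {name!r}")
            model.molecules[name] = MoleculeDef(
                name=name, sites=tuple(sites), compartments=comps, symmetric=sym
            )

        elif block == "seed species":
            parts = line.rsplit(None, 1)
            if len(parts) != 2:
                raise ParseError(lineno, "expected: species amount")
            pat = parse_pattern(parts[0], lineno)
            sp = _pattern_to_species(pat, model.molecules, lineno)
            model.seeds.append(SeedSpec(species=sp, amount_expr=parts[1]))

        elif block == "observables":
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(lineno, "expected: name pattern [pattern ...]")
            pats = [parse_pattern(p, lineno) for p in parts[1:]]
            model.observables.append(ObservableDef(name=parts[0], patterns=pats))

        elif block == "reaction rules":
            m = re.match(r"^(?P<id>[\w.-]+)\s*:\s*(?P<body>.*)$", line)
            if not m:
                raise ParseError(lineno, "expected: id: lhs -> rhs rate")
            body = m.group("body")
            reversible = "<->" in body
            arrow = "<->" if reversible else "->"
            if arrow not in body:
                raise ParseError(lineno, "rule has no arrow")
            lhs_text, rest = body.split(arrow, 1)
            toks = rest.strip().split()
            if len(toks) < 2:
                raise ParseError(lineno, "rule is missing a rate")
            # patterns contain no whitespace; complexes are joined by a
            # free-standing '+', everything after them is the rate expression
            rhs_toks = [toks[0]]
            i = 1
            while i + 1 < len(toks) and toks[i] == "+":
                rhs_toks.append(toks[i + 1])
                i += 2
            rate_text = "".join(toks[i:])
            if reversible:
                rates = [r.strip() for r in rate_text.split(",")]
                if len(rates) != 2 or not all(rates):
                    raise ParseError(lineno, "reversible rule needs 'kf, kr'")
                kf, kr = rates
            else:
                if "," in rate_text:
                    raise ParseError(lineno, "irreversible rule takes one rate")
                kf, kr = rate_text.strip(), None

            def _split_complexes(text: str) -> list[str]:
                parts = re.split(r"\s+\+\s+", text.strip())
                return [p for p in parts if p]

            lhs = [parse_pattern(p, lineno) for p in _split_complexes(lhs_text)]
            rhs = [parse_pattern(p, lineno) for p in rhs_toks]
            if not 1 <= len(lhs) <= 2:
                raise ParseError(lineno, "rules take one or two reactant complexes")
            rl = RuleLine(
                rule_id=m.group("id"),
                reversible=reversible,
                lhs=lhs,
                rhs=rhs,
                rate_forward=kf,
                rate_reverse=kr,
                lineno=lineno,
            )
            model.rule_lines.append(rl)
            try:
                model.rules.extend(_expand_rule_line(rl))
            except RuleDefinitionError as exc:
                raise ParseError(lineno, str(exc)) from exc

    if block is not None:
        raise ParseError(0, f"unterminated block {block!r}")
    for rule in model.rules:
        rule.validate(model.molecules)
    return model


def _pattern_to_species(pat, molecules, lineno: int) -> Species:
    """Seed species are fully specified patterns; convert and canonicalize."""
    mols = []
    bond_ends: dict[int, list[tuple[int, str]]] = {}
    for mi, pm in enumerate(pat.mols):
        if pm.name not in molecules:
            raise ParseError(lineno, f"unknown molecule {pm.name!r}")
        mdef = molecules[pm.name]
        states = {}
        listed = set()
        for site, (state, bond) in pm.sites:
            listed.add(site)
            sdef = mdef.site(site)
            if sdef.states:
                if state is None:
                    raise ParseError(
                        lineno, f"seed species must fix the state of {pm.name}.{site}"
                    )
                states[site] = state
            if isinstance(bond, int):
                bond_ends.setdefault(bond, []).append((mi, site))
            elif bond not in (FREE,):
                raise ParseError(lineno, "seed species may not carry bond wildcards")
        missing = set(mdef.site_names) - listed
        if missing:
            raise ParseError(
                lineno, f"seed species must list all sites of {pm.name} (missing {sorted(missing)})"
            )
        mols.append((pm.name, states))
    bonds = []
    for ends in bond_ends.values():
        if len(ends) != 2:
            raise ParseError(lineno, "dangling bond in seed species")
        (i, si), (j, sj) = ends
        bonds.append((i, si, j, sj))
    comp = pat.compartment
    if comp is None:
        raise ParseError(lineno, "seed species must carry a compartment tag")
    return make_species(molecules, mols, bonds, comp)
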