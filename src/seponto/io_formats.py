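"""Readers/writers for the release formats, and the command-line interface.

Two on-disk dialects are supported:

* a simplified RF2-style release: three UTF-8, tab-delimited, LF-terminated
  files (``concepts.tsv``, ``descriptions.tsv``, ``axioms.tsv``) with header
  rows and id-sorted content.  The dialect intentionally omits release-
  management columns (effectiveTime, moduleId, active); it is not conformant
  RF2 but is trivially convertible.
* an OWL 2 functional-syntax subset covering exactly the EL constructs the
  model uses: Declaration, AnnotationAssertion, SubClassOf,
  EquivalentClasses, ObjectIntersectionOf, ObjectSomeValuesFrom,
  SubObjectPropertyOf (including ObjectPropertyChain) and
  TransitiveObjectProperty.  Anything else is rejected by name and line.

Both writers are byte-stable: writing the same ontology twice produces
identical bytes (rows sorted, no floats, fixed prefixes).  Axioms inside the
RF2 axiom table reuse the functional-syntax serialization, one axiom per
row, which avoids a second expression grammar.
"""

from __future__ import annotations

import argparse
import logging
import sys
from pathlib import Path

from .core_model import (
    Axiom,
    AxiomKind,
    ConceptRef,
    Conjunction,
    Existential,
    Named,
    Ontology,
    OntologyError,
    Role,
    RoleChain,
    SemanticClass,
    canonical,
)

log = logging.getLogger("seponto")

RF2_FILES = ("concepts.tsv", "descriptions.tsv", "axioms.tsv")
_DESC_TYPES = ("FSN", "preferred", "synonym")


class FormatError(OntologyError):
    """Malformed input file (carries file and line context in the message)."""


# ---------------------------------------------------------------------------
# Functional-syntax serialization
# ---------------------------------------------------------------------------

def expr_to_ofn(expr) -> str:
    if isinstance(expr, Named):
        return f":{expr.concept}"
    if isinstance(expr, Existential):
        return f"ObjectSomeValuesFrom(:{expr.role} {expr_to_ofn(expr.filler)})"
    if isinstance(expr, Conjunction):
        inner = " ".join(
            expr_to_ofn(op) for op in sorted(expr.operands, key=canonical)
        )
        return f"ObjectIntersectionOf({inner})"
    raise FormatError(f"cannot serialize expression of type {type(expr).__name__}")


def axiom_to_ofn(ax: Axiom) -> str:
    if ax.kind is AxiomKind.EQUIVALENT:
        return f"EquivalentClasses({expr_to_ofn(ax.left)} {expr_to_ofn(ax.right)})"
    return f"SubClassOf({expr_to_ofn(ax.left)} {expr_to_ofn(ax.right)})"


def _quote(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def role_rows(ont: Ontology) -> list:
    """Functional-syntax rows declaring the role box (sorted, stable)."""
    rows = []
    for rid in sorted(ont.roles):
        role = ont.roles[rid]
        rows.append(f"Declaration(ObjectProperty(:{rid}))")
        rows.append(f"AnnotationAssertion(rdfs:label :{rid} {_quote(role.name)})")
        if role.parent:
            rows.append(f"SubObjectPropertyOf(:{rid} :{role.parent})")
        if role.transitive:
            rows.append(f"TransitiveObjectProperty(:{rid})")
    for ch in sorted(ont.chains, key=lambda c: (c.lhs, c.rhs)):
        rows.append(
            "SubObjectPropertyOf(ObjectPropertyChain("
            f":{ch.lhs[0]} :{ch.lhs[1]}) :{ch.rhs})"
        )
    return rows


# ---------------------------------------------------------------------------
# Functional-syntax parsing (recursive descent over a tiny token stream)
# ---------------------------------------------------------------------------

def _tokenize(text: str):
    """Yield (token, line); tokens are '(', ')', quoted strings or atoms."""
    line = 1
    i = 0
    n = len(text)
    while i < n:
        c = text[i]
        if c == "\n":
            line += 1
            i += 1
        elif c in " \t\r":
            i += 1
        elif c in "()":
            yield c, line
            i += 1
        elif c == '"':
            j = i + 1
            out = []
            while j < n and text[j] != '"':
                if text[j] == "\\" and j + 1 < n:
                    out.append(text[j + 1])
                    j += 2
                else:
                    out.append(text[j])
                    j += 1
            if j >= n:
                raise FormatError(f"unterminated string literal at line {line}")
            yield '"' + "".join(out), line
            i = j + 1
        else:
            j = i
            while j < n and text[j] not in ' \t\r\n()"':
                j += 1
            yield text[i:j], line
            i = j


class _Parser:
    def __init__(self, text: str, source: str = "<input>"):
        self.tokens = list(_tokenize(text))
        self.pos = 0
        self.source = source

    def eof(self) -> bool:
        return self.pos >= len(self.tokens)

    def peek(self):
        return self.tokens[self.pos]

    def next(self):
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def error(self, msg: str, line: int):
        raise FormatError(f"{self.source}:{line}: {msg}")

    def parse_form(self):
        """Return ('call', name, args, line) or ('atom', text, line)."""
        tok, line = self.next()
        if tok in ("(", ")"):
            self.error(f"unexpected {tok!r}", line)
        if tok.startswith('"'):
            return ("str", tok[1:], line)
        if not self.eof() and self.peek()[0] == "(":
            self.next()  # consume '('
            args = []
            while True:
                if self.eof():
                    self.error(f"unclosed {tok}(", line)
                if self.peek()[0] == ")":
                    self.next()
                    break
                args.append(self.parse_form())
            return ("call", tok, args, line)
        return ("atom", tok, line)

    def parse_all(self):
        forms = []
        while not self.eof():
            forms.append(self.parse_form())
        return forms


def _local(atom: str, line: int, source: str) -> str:
    if not atom.startswith(":"):
        raise FormatError(f"{source}:{line}: expected a ':'-prefixed id, got {atom!r}")
    return atom[1:]


def _form_to_expr(form, source: str):
    kind = form[0]
    if kind == "atom":
        return Named(_local(form[1], form[2], source))
    if kind != "call":
        raise FormatError(f"{source}:{form[2]}: unexpected literal in expression")
    name, args, line = form[1], form[2], form[3]
    if name == "ObjectSomeValuesFrom":
        if len(args) != 2 or args[0][0] != "atom":
            raise FormatError(f"{source}:{line}: malformed ObjectSomeValuesFrom")
        role = _local(args[0][1], args[0][2], source)
        return Existential(role, _form_to_expr(args[1], source))
    if name == "ObjectIntersectionOf":
        if len(args) < 2:
            raise FormatError(
                f"{source}:{line}: ObjectIntersectionOf needs >= 2 operands"
            )
        return Conjunction(frozenset(_form_to_expr(a, source) for a in args))
    raise FormatError(
        f"{source}:{line}: unsupported OWL construct {name!r} (EL subset only)"
    )


class _OntologyAssembler:
    """Accumulates parsed declarations and builds a validated Ontology."""

    def __init__(self, source: str):
        self.source = source
        self.concept_ids: list = []
        self.concept_meta: dict = {}   # id -> dict
        self.role_ids: list = []
        self.role_meta: dict = {}
        self.chains: list = []
        self.axioms: list = []         # (Axiom, line)
        self.annotations: list = []    # (prop, ident, value, line)

    def _meta(self, cid: str) -> dict:
        return self.concept_meta.setdefault(
            cid, {"fsn": "", "preferred": "", "synonyms": [],
                  "semantic_class": SemanticClass.OTHER},
        )

    def _role(self, rid: str) -> dict:
        return self.role_meta.setdefault(
            rid, {"name": rid, "parent": None, "transitive": False},
        )

    def handle(self, form) -> None:
        if form[0] != "call":
            return  # stray atoms (e.g. the ontology IRI) are ignored
        name, args, line = form[1], form[2], form[3]
        src = self.source
        if name == "Prefix":
            return
        if name == "Ontology":
            for child in args:
                self.handle(child)
            return
        if name == "Declaration":
            inner = args[0]
            if inner[0] != "call":
                raise FormatError(f"{src}:{line}: malformed Declaration")
            dkind, dargs = inner[1], inner[2]
            ident = _local(dargs[0][1], dargs[0][2], src)
            if dkind == "Class":
                if ident not in self.concept_meta:
                    self.concept_ids.append(ident)
                self._meta(ident)
            elif dkind == "ObjectProperty":
                if ident not in self.role_meta:
                    self.role_ids.append(ident)
                self._role(ident)
            else:
                raise FormatError(
                    f"{src}:{line}: unsupported declaration {dkind!r}"
                )
            return
        if name == "AnnotationAssertion":
            prop = args[0][1]
            ident = _local(args[1][1], args[1][2], src)
            value = args[2][1]
            # applied at build time: declarations may follow in sorted input
            self.annotations.append((prop, ident, value, line))
            return
        if name == "SubObjectPropertyOf":
            if args[0][0] == "call" and args[0][1] == "ObjectPropertyChain":
                chain_args = args[0][2]
                lhs = tuple(_local(a[1], a[2], src) for a in chain_args)
                rhs = _local(args[1][1], args[1][2], src)
                if len(lhs) != 2:
                    raise FormatError(
                        f"{src}:{line}: only binary property chains supported"
                    )
                self.chains.append(RoleChain(lhs, rhs))
            else:
                child = _local(args[0][1], args[0][2], src)
                parent = _local(args[1][1], args[1][2], src)
                self._role(child)["parent"] = parent
                if child not in self.role_ids:
                    self.role_ids.append(child)
            return
        if name == "TransitiveObjectProperty":
            rid = _local(args[0][1], args[0][2], src)
            self._role(rid)["transitive"] = True
            if rid not in self.role_ids:
                self.role_ids.append(rid)
            return
        if name == "SubClassOf":
            if len(args) != 2:
                raise FormatError(f"{src}:{line}: malformed SubClassOf")
            ax = Axiom(
                AxiomKind.SUBCLASS_OF,
                _form_to_expr(args[0], src),
                _form_to_expr(args[1], src),
            )
            self.axioms.append((ax, line))
            return
        if name == "EquivalentClasses":
            if len(args) != 2 or args[0][0] != "atom":
                raise FormatError(
                    f"{src}:{line}: EquivalentClasses must be "
                    "(name, definition)"
                )
            ax = Axiom(
                AxiomKind.EQUIVALENT,
                Named(_local(args[0][1], args[0][2], src)),
                _form_to_expr(args[1], src),
            )
            self.axioms.append((ax, line))
            return
        raise FormatError(
            f"{src}:{line}: unsupported OWL construct {name!r} (EL subset only)"
        )

    def _apply_annotations(self) -> None:
        for prop, ident, value, line in self.annotations:
            if ident in self.role_meta:
                if prop == "rdfs:label":
                    self.role_meta[ident]["name"] = value
                else:
                    log.warning(
                        "%s:%d: ignoring role annotation %s", self.source,
                        line, prop,
                    )
                continue
            if ident not in self.concept_meta:
                log.warning(
                    "%s:%d: annotation on undeclared id %r ignored",
                    self.source, line, ident,
                )
                continue
            meta = self._meta(ident)
            if prop == "rdfs:label":
                meta["fsn"] = value
            elif prop == "skos:prefLabel":
                meta["preferred"] = value
            elif prop == "skos:altLabel":
                meta["synonyms"].append(value)
            elif prop == ":semanticClass":
                try:
                    meta["semantic_class"] = SemanticClass(value)
                except ValueError:
                    raise FormatError(
                        f"{self.source}:{line}: unknown semantic class {value!r}"
                    ) from None
            else:
                log.warning(
                    "%s:%d: ignoring annotation %s", self.source, line, prop
                )

    def build(self, *, primitive_flags: dict = None) -> Ontology:
        self._apply_annotations()
        ont = Ontology()
        for rid in self.role_ids:
            meta = self.role_meta[rid]
            ont.add_role(Role(
                id=rid, name=meta["name"], parent=meta["parent"],
                transitive=meta["transitive"],
            ))
        defined = {
            ax.left.concept for ax, _ in self.axioms
            if ax.kind is AxiomKind.EQUIVALENT
        }
        for cid in self.concept_ids:
            meta = self.concept_meta[cid]
            primitive = cid not in defined
            if primitive_flags is not None and cid in primitive_flags:
                if primitive_flags[cid] != primitive:
                    raise FormatError(
                        f"{self.source}: concept {cid!r} primitive flag "
                        "contradicts its axioms"
                    )
            ont.add_concept(ConceptRef(
                id=cid,
                fsn=meta["fsn"] or f"{cid} (unnamed)",
                preferred_term=meta["preferred"],
                synonyms=tuple(meta["synonyms"]),
                primitive=primitive,
                semantic_class=meta["semantic_class"],
            ))
        for ch in self.chains:
            ont.add_chain(ch)
        for ax, line in self.axioms:
            try:
                ont.add_axiom(ax)
            except OntologyError as exc:
                raise FormatError(f"{self.source}:{line}: {exc}") from exc
        ont.validate()
        return ont


# ---------------------------------------------------------------------------
# RF2-style dialect
# ---------------------------------------------------------------------------

def write_rf2(ont: Ontology, directory) -> None:
    """Write the three-table release bundle (byte-stable)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    rows = ["id\tprimitive\tsemanticClass"]
    for cid in sorted(ont.concepts):
        c = ont.concepts[cid]
        rows.append(f"{cid}\t{int(c.primitive)}\t{c.semantic_class.value}")
    (directory / "concepts.tsv").write_text("\n".join(rows) + "\n", "utf-8")

    rows = ["conceptId\tterm\ttype"]
    desc = []
    for cid in sorted(ont.concepts):
        c = ont.concepts[cid]
        desc.append((cid, 0, c.fsn))
        if c.preferred_term:
            desc.append((cid, 1, c.preferred_term))
        for syn in sorted(c.synonyms):
            desc.append((cid, 2, syn))
    for cid, tidx, term in sorted(desc):
        rows.append(f"{cid}\t{term}\t{_DESC_TYPES[tidx]}")
    (directory / "descriptions.tsv").write_text("\n".join(rows) + "\n", "utf-8")

    rows = ["axiom"]
    body = sorted(role_rows(ont)) + sorted(axiom_to_ofn(ax) for ax in ont.axioms)
    rows.extend(body)
    (directory / "axioms.tsv").write_text("\n".join(rows) + "\n", "utf-8")


def _read_tsv(path: Path, expected_cols):
    text = path.read_text("utf-8")
    lines = text.split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    if not lines:
        raise FormatError(f"{path}: empty file (missing header)")
    header = lines[0].split("\t")
    for col in expected_cols:
        if col not in header:
            raise FormatError(f"{path}:1: missing column {col!r}")
    extra = [c for c in header if c not in expected_cols]
    if extra:
        log.warning("%s: ignoring unknown columns %s", path, extra)
    idx = {col: header.index(col) for col in expected_cols}
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) < len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(parts)}"
            )
        yield lineno, {col: parts[i] for col, i in idx.items()}


def read_rf2(directory) -> Ontology:
    """Read a three-table bundle back into an Ontology."""
    directory = Path(directory)
    for fname in RF2_FILES:
        if not (directory / fname).exists():
            raise FormatError(f"{directory}: missing required file {fname}")

    asm = _OntologyAssembler(str(directory / "axioms.tsv"))
    primitive_flags = {}
    concepts_path = directory / "concepts.tsv"
    for lineno, row in _read_tsv(concepts_path, ("id", "primitive", "semanticClass")):
        cid = row["id"]
        if cid in asm.concept_meta:
            raise FormatError(f"{concepts_path}:{lineno}: duplicate id {cid!r}")
        asm.concept_ids.append(cid)
        meta = asm._meta(cid)
        try:
            meta["semantic_class"] = SemanticClass(row["semanticClass"])
            primitive_flags[cid] = bool(int(row["primitive"]))
        except ValueError as exc:
            raise FormatError(f"{concepts_path}:{lineno}: {exc}") from exc

    desc_path = directory / "descriptions.tsv"
    for lineno, row in _read_tsv(desc_path, ("conceptId", "term", "type")):
        cid = row["conceptId"]
        if cid not in asm.concept_meta:
            raise FormatError(
                f"{desc_path}:{lineno}: description references undeclared "
                f"concept {cid!r}"
            )
        meta = asm._meta(cid)
        dtype = row["type"]
        if dtype == "FSN":
            meta["fsn"] = row["term"]
        elif dtype == "preferred":
            meta["preferred"] = row["term"]
        elif dtype == "synonym":
            meta["synonyms"].append(row["term"])
        else:
            raise FormatError(
                f"{desc_path}:{lineno}: unknown description type {dtype!r}"
            )

    ax_path = directory / "axioms.tsv"
    for lineno, row in _read_tsv(ax_path, ("axiom",)):
        text = row["axiom"].strip()
        if not text:
            continue
        parser = _Parser(text, f"{ax_path}:{lineno}")
        for form in parser.parse_all():
            asm.handle(form)
    return asm.build(primitive_flags=primitive_flags)


# ---------------------------------------------------------------------------
# OWL functional-syntax documents
# ---------------------------------------------------------------------------

_OFN_HEADER = [
    "Prefix(:=<http://example.org/seponto#>)",
    "Prefix(rdfs:=<http://www.w3.org/2000/01/rdf-schema#>)",
    "Prefix(skos:=<http://www.w3.org/2004/02/skos/core#>)",
    "Ontology(<http://example.org/seponto>",
]


def write_ofn(ont: Ontology, path) -> None:
    """Write the ontology as an OWL functional-syntax document (byte-stable)."""
    lines = list(_OFN_HEADER)
    for cid in sorted(ont.concepts):
        c = ont.concepts[cid]
        lines.append(f"Declaration(Class(:{cid}))")
        lines.append(f"AnnotationAssertion(rdfs:label :{cid} {_quote(c.fsn)})")
        if c.preferred_term:
            lines.append(
                f"AnnotationAssertion(skos:prefLabel :{cid} "
                f"{_quote(c.preferred_term)})"
            )
        for syn in sorted(c.synonyms):
            lines.append(
                f"AnnotationAssertion(skos:altLabel :{cid} {_quote(syn)})"
            )
        lines.append(
            f"AnnotationAssertion(:semanticClass :{cid} "
            f"{_quote(c.semantic_class.value)})"
        )
    lines.extend(role_rows(ont))
    lines.extend(sorted(axiom_to_ofn(ax) for ax in ont.axioms))
    lines.append(")")
    Path(path).write_text("\n".join(lines) + "\n", "utf-8")


def read_ofn(path) -> Ontology:
    """Parse an OWL functional-syntax subset document."""
    path = Path(path)
    asm = _OntologyAssembler(str(path))
    parser = _Parser(path.read_text("utf-8"), str(path))
    for form in parser.parse_all():
        asm.handle(form)
    return asm.build()


# ---------------------------------------------------------------------------
# Config files
# ---------------------------------------------------------------------------

def read_config(path) -> dict:
    """Parse a minimal key=value config file ('#' starts a comment line)."""
    out = {}
    for lineno, line in enumerate(Path(path).read_text("utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected key=value")
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out


# ---------------------------------------------------------------------------
# Command-line interface
# ---------------------------------------------------------------------------

def _load(path_str: str) -> Ontology:
    path = Path(path_str)
    if path.is_dir():
        return read_rf2(path)
    if path.suffix == ".ofn":
        return read_ofn(path)
    raise FormatError(
        f"{path}: expected an RF2 bundle directory or a .ofn file"
    )


def _save(ont: Ontology, path_str: str, fmt: str) -> None:
    if fmt == "rf2":
        write_rf2(ont, path_str)
    else:
        write_ofn(ont, path_str)


def cli(argv=None) -> int:
    """Entry point for the ``seponto`` command; returns an exit code."""
    parser = argparse.ArgumentParser(
        prog="seponto",
        description=(
            "SEP-model meronymic reasoning over EL ontologies of regional "
            "anatomy"
        ),
    )
    parser.add_argument("--log-level", default="WARNING")
    parser.add_argument(
        "--config", default=None,
        help="key=value config file (output_dir, namespace)",
    )
    sub = parser.add_subparsers(dest="command", required=True)

    p = sub.add_parser("build-trunk", help="emit the trunk anatomy fixture")
    p.add_argument("--out", default=None)
    p.add_argument("--format", choices=("rf2", "ofn"), default="rf2")

    p = sub.add_parser("classify", help="classify an ontology to taxonomy TSV")
    p.add_argument("input")
    p.add_argument("--out", default=None)
    p.add_argument("--full", action="store_true",
                   help="emit the full closure instead of direct parents")

    p = sub.add_parser("entails", help="test one subsumption (exit 0 iff it holds)")
    p.add_argument("input")
    p.add_argument("sub")
    p.add_argument("super")

    p = sub.add_parser("diff", help="impact diff between two ontologies")
    p.add_argument("before")
    p.add_argument("after")
    p.add_argument("--filter", action="append", default=None,
                   help="semantic class filter (repeatable), e.g. disorder")
    p.add_argument("--tsv", action="store_true",
                   help="machine-readable tab-delimited output")

    p = sub.add_parser("export", help="convert between rf2 and ofn")
    p.add_argument("input")
    p.add_argument("out")
    p.add_argument("--to", choices=("rf2", "ofn"), required=True)

    p = sub.add_parser("generate", help="emit a seeded random EL ontology")
    p.add_argument("--seed", type=int, default=0)
    p.add_argument("--out", required=True)
    p.add_argument("--n-concepts", type=int, default=8)
    p.add_argument("--n-roles", type=int, default=2)
    p.add_argument("--n-axioms", type=int, default=12)

    args = parser.parse_args(argv)
    logging.basicConfig(level=args.log_level.upper())
    config = read_config(args.config) if args.config else {}

    from .el_reasoner import classify, entails
    from .impact_qa import diff_taxonomies, impact_report, impact_table

    try:
        if args.command == "build-trunk":
            from .trunk_model import build_trunk_ontology

            out = args.out or config.get("output_dir") or "trunk"
            _save(build_trunk_ontology(), out, args.format)
            print(f"wrote trunk fixture to {out}")
            return 0

        if args.command == "classify":
            taxonomy = classify(_load(args.input))
            lines = ["sub\tsuper"]
            if args.full:
                pairs = sorted(p for p in taxonomy.closure if p[0] != p[1])
            else:
                pairs = sorted(
                    (rep, parent)
                    for rep, parents in taxonomy.direct.items()
                    for parent in parents
                )
            lines += [f"{a}\t{b}" for a, b in pairs]
            text = "\n".join(lines) + "\n"
            if args.out:
                Path(args.out).write_text(text, "utf-8")
            else:
                sys.stdout.write(text)
            return 0

        if args.command == "entails":
            ont = _load(args.input)
            holds = entails(ont, args.sub, getattr(args, "super"))
            print(f"{args.sub} {'<=' if holds else '</='} {getattr(args, 'super')}")
            return 0 if holds else 1

        if args.command == "diff":
            before = _load(args.before)
            after = _load(args.after)
            diff = diff_taxonomies(
                classify(before), classify(after),
                ontology=after, filter_classes=args.filter,
            )
            if args.tsv:
                sys.stdout.write(impact_table(diff))
            else:
                print(impact_report(diff, ontology=after))
            return 0

        if args.command == "export":
            _save(_load(args.input), args.out, args.to)
            return 0

        if args.command == "generate":
            from .synthetic import GenConfig, generate

            cfg = GenConfig(
                n_concepts=args.n_concepts, n_roles=args.n_roles,
                n_axioms=args.n_axioms, seed=args.seed,
            )
            write_rf2(generate(cfg), args.out)
            print(f"wrote synthetic ontology to {args.out}")
            return 0
    except (OntologyError, OSError, ValueError) as exc:
        print(f"error: {exc}", file=sys.stderr)
        return 2
    return 2


def main() -> None:  # console-script entry point
    raise SystemExit(cli())
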