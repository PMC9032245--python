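"""Gene-protein-reaction (GPR) association expressions.

A GPR is a boolean expression over gene identifiers stating which gene
products (possibly acting as enzyme complexes) enable a reaction.  AND
nodes model complexes whose every component is required; OR nodes model
isoenzymes.  The empty expression means "no gene association" and, by
convention, evaluates to true so that spontaneous or orphan reactions
are never blocked by gene presence filters.
"""

from __future__ import annotations

import re
from typing import Iterable, Union

# Internal node forms: None (empty), str (gene leaf) or
# (op, (child, child, ...)) with op in {"and", "or"} and >= 2 children.
_Node = Union[None, str, tuple]

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class GprSyntaxError(ValueError):
    """Raised when a GPR string cannot be parsed."""


def _normalize(node: _Node) -> _Node:
    """Flatten nested same-op nodes and collapse single-child nodes."""
    if node is None or isinstance(node, str):
        return node
    op, children = node
    flat: list[_Node] = []
    for child in children:
        child = _normalize(child)
        if isinstance(child, tuple) and child[0] == op:
            flat.extend(child[1])
        else:
            flat.append(child)
    # deduplicate while preserving order
    seen: list[_Node] = []
    for c in flat:
        if c not in seen:
            seen.append(c)
    if len(seen) == 1:
        return seen[0]
    return (op, tuple(seen))


class Gpr:
    """A boolean gene-association expression tree.

    Construct with :meth:`parse` ("(b0001 and b0002) or b0003"),
    :meth:`empty`, or the combinators :meth:`all_of` / :meth:`any_of`.
    """

    __slots__ = ("_root",)

    def __init__(self, root: _Node = None):
        self._root = _normalize(root)

    # -- constructors -------------------------------------------------
    @classmethod
    def empty(cls) -> "Gpr":
        return cls(None)

    @classmethod
    def gene(cls, gene_id: str) -> "Gpr":
        if not gene_id:
            raise ValueError("gene id must be non-empty")
        return cls(gene_id)

    @classmethod
    def all_of(cls, parts: Iterable["Gpr"]) -> "Gpr":
        parts = [p for p in parts if not p.is_empty]
        if not parts:
            return cls.empty()
        if len(parts) == 1:
            return parts[0]
        return cls(("and", tuple(p._root for p in parts)))

    @classmethod
    def any_of(cls, parts: Iterable["Gpr"]) -> "Gpr":
        parts = [p for p in parts if not p.is_empty]
        if not parts:
            return cls.empty()
        if len(parts) == 1:
            return parts[0]
        return cls(("or", tuple(p._root for p in parts)))

    @classmethod
    def parse(cls, text: str) -> "Gpr":
        """Parse a textual GPR ('and'/'or' case-insensitive, parentheses).

        AND binds tighter than OR, the usual convention in model files.
        """
        if text is None or not text.strip():
            return cls.empty()
        tokens = _TOKEN_RE.findall(text)
        pos = 0

        def peek() -> str | None:
            return tokens[pos] if pos < len(tokens) else None

        def take() -> str:
            nonlocal pos
            tok = tokens[pos]
            pos += 1
            return tok

        def parse_or() -> _Node:
            parts = [parse_and()]
            while peek() is not None and peek().lower() == "or":
                take()
                parts.append(parse_and())
            return parts[0] if len(parts) == 1 else ("or", tuple(parts))

        def parse_and() -> _Node:
            parts = [parse_atom()]
            while peek() is not None and peek().lower() == "and":
                take()
                parts.append(parse_atom())
            return parts[0] if len(parts) == 1 else ("and", tuple(parts))

        def parse_atom() -> _Node:
            tok = peek()
            if tok is None:
                raise GprSyntaxError(f"unexpected end of GPR: {text!r}")
            if tok == "(":
                take()
                inner = parse_or()
                if peek() != ")":
                    raise GprSyntaxError(f"unbalanced parentheses in {text!r}")
                take()
                return inner
            if tok == ")" or tok.lower() in ("and", "or"):
                raise GprSyntaxError(f"unexpected token {tok!r} in {text!r}")
            return take()

        root = parse_or()
        if pos != len(tokens):
            raise GprSyntaxError(f"trailing tokens in GPR: {text!r}")
        return cls(root)

    # -- queries ------------------------------------------------------
    @property
    def is_empty(self) -> bool:
        return self._root is None

    def genes(self) -> frozenset[str]:
        """All gene ids appearing in the expression."""
        out: set[str] = set()

        def walk(node: _Node) -> None:
            if node is None:
                return
            if isinstance(node, str):
                out.add(node)
                return
            for child in node[1]:
                walk(child)

        walk(self._root)
        return frozenset(out)

    def evaluate(self, present_genes: Iterable[str]) -> bool:
        """True iff the expression is satisfied by the given gene set.

        The empty expression evaluates to true (spontaneous reactions
        pass any gene filter).
        """
        present = set(present_genes)

        def ev(node: _Node) -> bool:
            if node is None:
                return True
            if isinstance(node, str):
                return node in present
            op, children = node
            if op == "and":
                return all(ev(c) for c in children)
            return any(ev(c) for c in children)

        return ev(self._root)

    def map_genes(self, fn) -> "Gpr":
        """Rewrite every leaf with ``fn(gene_id) -> Gpr``."""

        def walk(node: _Node) -> _Node:
            if node is None:
                return None
            if isinstance(node, str):
                return fn(node)._root
            op, children = node
            return (op, tuple(walk(c) for c in children))

        return Gpr(walk(self._root))

    def prune_to(self, present_genes: Iterable[str]) -> "Gpr":
        """Drop branches unsatisfiable under ``present_genes``.

        OR children that evaluate false are removed; an AND node with any
        false child is removed as a whole (inside a parent OR).  If the
        full expression is unsatisfied the empty expression is returned.
        Useful when rewriting a reference GPR to the genes of a target
        organism: only the satisfied alternatives are kept.
        """
        present = set(present_genes)

        def walk(node: _Node) -> _Node | bool:
            # returns a node, or False when the branch is unsatisfied
            if node is None:
                return None
            if isinstance(node, str):
                return node if node in present else False
            op, children = node
            kept = [walk(c) for c in children]
            if op == "and":
                if any(k is False for k in kept):
                    return False
                return ("and", tuple(kept))
            kept = [k for k in kept if k is not False]
            if not kept:
                return False
            if len(kept) == 1:
                return kept[0]
            return ("or", tuple(kept))

        result = walk(self._root)
        return Gpr.empty() if result is False else Gpr(result)

    # -- formatting / identity ----------------------------------------
    def to_string(self) -> str:
        def fmt(node: _Node, parent_op: str | None) -> str:
            if isinstance(node, str):
                return node
            op, children = node
            joined = f" {op} ".join(fmt(c, op) for c in children)
            if parent_op is not None and op != parent_op:
                return f"({joined})"
            return joined

        if self._root is None:
            return ""
        return fmt(self._root, None)

    def _canonical(self, node: _Node = ...) -> object:
        if node is ...:
            node = self._root
        if node is None or isinstance(node, str):
            return node
        op, children = node
        return (op, tuple(sorted((repr(self._canonical(c)) for c in children))))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Gpr):
            return NotImplemented
        return self._canonical() == other._canonical()

    def __hash__(self) -> int:
        return hash(repr(self._canonical()))

    def __repr__(self) -> str:
        return f"Gpr({self.to_string()!r})" if not self.is_empty else "Gpr.empty()"
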