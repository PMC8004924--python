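"""A small atom-selection language over :class:`~lrabind.topology.Topology`.

Grammar (whitespace-separated tokens, case-sensitive keywords)::

    expr      := and_expr ( "or" and_expr )*
    and_expr  := unary ( "and" unary )*
    unary     := "not" unary | "(" expr ")" | primitive
    primitive := "ligand" | "protein" | "backbone" | "solvent" | "ions"
               | "residue" INT | "name" NAME | "within" FLOAT "of" unary

``backbone`` means atoms named N, CA, C, O of protein residues.  ``within
R of SEL`` keeps every atom whose distance to the nearest atom of SEL is
at most R Å (the reference atoms themselves are therefore included); it
requires a coordinate frame.  Selections are returned as ordered
(ascending) atom-index arrays, so they are deterministic and stable under
atom-order-preserving rewrites of the source file.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import cdist

from .topology import Topology

__all__ = ["make_selection", "SelectionError"]

_GROUP_KEYWORDS = ("ligand", "protein", "backbone", "solvent", "ions")


class SelectionError(ValueError):
    """Malformed selection expression."""


def _tokenize(expression: str) -> list[str]:
    return expression.replace("(", " ( ").replace(")", " ) ").split()


class _Parser:
    def __init__(self, tokens: list[str], topology: Topology,
                 coords: np.ndarray | None):
        self.tokens = tokens
        self.pos = 0
        self.top = topology
        self.coords = coords

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"trailing tokens at '{self.peek()}'")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() == "or":
            self.take()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.unary()
        while self.peek() == "and":
            self.take()
            mask = mask & self.unary()
        return mask

    def unary(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.take()
            return ~self.unary()
        if tok == "(":
            self.take()
            mask = self.expr()
            if self.take() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        return self.primitive()

    def primitive(self) -> np.ndarray:
        tok = self.take()
        if tok in _GROUP_KEYWORDS:
            masks = {
                "ligand": self.top.ligand_mask,
                "protein": self.top.protein_mask,
                "backbone": self.top.backbone_mask,
                "solvent": self.top.solvent_mask,
                "ions": self.top.ion_mask,
            }
            return masks[tok]()
        if tok == "residue":
            try:
                number = int(self.take())
            except ValueError as exc:
                raise SelectionError("'residue' needs an integer") from exc
            return self.top.res_id == number
        if tok == "name":
            return self.top.atom_name == self.take()
        if tok == "within":
            try:
                radius = float(self.take())
            except ValueError as exc:
                raise SelectionError("'within' needs a distance") from exc
            if self.take() != "of":
                raise SelectionError("expected 'of' after 'within R'")
            ref_mask = self.unary()
            if self.coords is None:
                raise SelectionError(
                    "'within' requires a coordinate frame (pass coords=)"
                )
            ref = np.flatnonzero(ref_mask)
            if len(ref) == 0:
                return np.zeros(self.top.n_atoms, dtype=bool)
            dmin = cdist(self.coords, self.coords[ref]).min(axis=1)
            return dmin <= radius
        raise SelectionError(f"unknown token '{tok}'")


def make_selection(
    topology: Topology, expression: str, coords: np.ndarray | None = None
) -> np.ndarray:
    """Evaluate a selection expression; return ascending atom indices.

    ``coords`` (one frame, shape ``(n_atoms, 3)``) is only needed for
    distance-based (``within``) terms.  An empty result is returned as-is
    with a warning — the caller decides whether that is an error.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _Parser(tokens, topology, coords).parse()
    indices = np.flatnonzero(mask)
    if len(indices) == 0:
        warnings.warn(f"selection '{expression}' matched no atoms")
    return indices
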