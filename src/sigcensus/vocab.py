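"""Domain vocabulary: mapping annotation dialects onto role tokens.

Domain tables mix Pfam accessions, Pfam names and SMART names depending on
how they were produced.  All classification rules in this package consume
*role tokens* ("HisKA", "REC", "GGDEF", ...); the :class:`DomainVocabulary`
translates whatever identifier appears in the input into a role token, so
naming dialects are a configuration concern, never a code change.
"""

from __future__ import annotations

import re
from importlib import resources
from typing import Optional

import yaml

from .model import DomainHit, ProteinArchitecture

_ACC_VERSION = re.compile(r"\.\d+$")


def _norm(identifier: str) -> str:
    """Normalize an accession/name: lowercase, strip accession version."""
    return _ACC_VERSION.sub("", identifier.strip()).lower()


class DomainVocabulary:
    """Bidirectional map between domain identifiers and role tokens.

    Parameters
    ----------
    roles:
        ``{role_token: [accepted accessions/names, ...]}``.  No identifier
        may be claimed by two role tokens.
    """

    def __init__(self, roles: dict[str, list[str]]):
        self.roles = {tok: list(ids) for tok, ids in roles.items()}
        self._lookup: dict[str, str] = {}
        for token, idents in self.roles.items():
            for ident in idents:
                key = _norm(ident)
                prev = self._lookup.get(key)
                if prev is not None and prev != token:
                    raise ValueError(
                        f"identifier {ident!r} mapped to both {prev!r} and {token!r}"
                    )
                self._lookup[key] = token

    # ------------------------------------------------------------------ query
    def role_of(self, hit: DomainHit) -> Optional[str]:
        """Role token for a hit, trying accession first, then name."""
        if hit.accession:
            tok = self._lookup.get(_norm(hit.accession))
            if tok is not None:
                return tok
        return self._lookup.get(_norm(hit.name))

    def role_of_name(self, identifier: str) -> Optional[str]:
        return self._lookup.get(_norm(identifier))

    def roles_of(self, arch: ProteinArchitecture) -> list[Optional[str]]:
        """Role token per retained domain, in architecture order."""
        return [self.role_of(h) for h in arch.domains]

    def role_set(self, arch: ProteinArchitecture) -> set[str]:
        return {r for r in self.roles_of(arch) if r is not None}

    def hits_with_role(self, arch: ProteinArchitecture, token: str) -> list[DomainHit]:
        return [h for h in arch.domains if self.role_of(h) == token]

    # ------------------------------------------------------------------- load
    @classmethod
    def from_yaml(cls, path) -> "DomainVocabulary":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(data["roles"])

    @classmethod
    def default(cls) -> "DomainVocabulary":
        """The vocabulary shipped with the package (Pfam + SMART dialects)."""
        ref = resources.files("sigcensus.data").joinpath("vocabulary.yaml")
        data = yaml.safe_load(ref.read_text())
        return cls(data["roles"])


def load_qs_vocabulary(path=None) -> dict[str, dict[str, list[str]]]:
    """Load the quorum-sensing screen vocabulary.

    Returns ``{pathway: {"synthase": [...], "receptor": [...]}}``.
    """
    if path is None:
        ref = resources.files("sigcensus.data").joinpath("qs_vocabulary.yaml")
        data = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    return data["pathways"]
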