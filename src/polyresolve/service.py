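"""HTTP GET endpoint for name standardization.

The service accepts the same query parameters a user would put in a GET
payload — ``polfil`` and ``ChemicalName`` required; ``Abbreviation``,
``TradeName`` and ``SMILES`` optional, names case-sensitive for drop-in
compatibility — and answers:

* ``200`` with ``{"StandardName", "density", "uSMILES"}`` when the vote
  resolves (density rendered as decimal text, g/cm³ at 25 °C);
* ``404`` with a fixed plain-text message when no candidate is found *or*
  the vote ties (the distinction lives in the unresolved-query log, which
  stands in for notifying an administrator);
* ``400`` with a field-level message for missing/invalid required
  parameters.  The handler never raises on malformed input.

``handle_get`` is a pure function of (params, corpus, weights) so the
contract is testable without a running server; ``make_wsgi_app`` wraps it
as a WSGI application served by the standard library's ``wsgiref``.  An
optional static bearer token can guard the endpoint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping
from urllib.parse import parse_qs
from wsgiref.simple_server import make_server

from .corpus import Corpus, load_corpus_jsonl
from .match import DEFAULT_WEIGHTS, QueryLog, SearchPackage, resolve

__all__ = [
    "NOT_FOUND_MESSAGE",
    "ServiceConfig",
    "handle_get",
    "make_wsgi_app",
    "serve",
    "format_density",
]

NOT_FOUND_MESSAGE = (
    "No results found. Admin alerted to update the database. "
    "Please try again in a week."
)

_STATUS_LINES = {200: "200 OK", 400: "400 Bad Request", 401: "401 Unauthorized", 404: "404 Not Found"}


@dataclass
class ServiceConfig:
    """Server configuration, loadable from a JSON file."""

    corpus_path: str
    weights_path: str | None = None
    epsilon: float = 0.1
    w_max: float = 4.0
    log_path: str | None = None
    token: str | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "ServiceConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def format_density(density: float | None) -> str:
    """Render a density as decimal text ("1.04"), empty when unknown."""
    if density is None:
        return ""
    return format(density, "g")


def handle_get(
    params: Mapping[str, str],
    corpus: Corpus,
    w=DEFAULT_WEIGHTS,
    log: QueryLog | None = None,
) -> tuple[int, dict | str]:
    """Answer one GET request; returns (status code, JSON body or message)."""
    polfil = params.get("polfil")
    if polfil not in ("pol", "fil"):
        return 400, {"error": "polfil is required and must be 'pol' or 'fil'"}
    name = params.get("ChemicalName", "").strip()
    if not name:
        return 400, {"error": "ChemicalName is a required parameter"}
    sp = SearchPackage(
        polfil=polfil,
        chemical_name=name,
        abbreviation=params.get("Abbreviation") or None,
        trade_name=params.get("TradeName") or None,
        smiles=params.get("SMILES") or None,
    )
    res = resolve(sp, corpus, w, log=log)
    if res.status != "resolved":
        return 404, NOT_FOUND_MESSAGE
    rec = corpus.records[res.winner]
    return 200, {
        "StandardName": rec.standard_name,
        "density": format_density(rec.density),
        "uSMILES": rec.usmiles or "",
    }


def make_wsgi_app(
    corpus: Corpus,
    w=DEFAULT_WEIGHTS,
    log: QueryLog | None = None,
    token: str | None = None,
):
    """Wrap :func:`handle_get` as a WSGI application."""

    def app(environ, start_response):
        if token is not None:
            auth = environ.get("HTTP_AUTHORIZATION", "")
            if auth != f"Bearer {token}":
                start_response(_STATUS_LINES[401], [("Content-Type", "application/json")])
                return [json.dumps({"error": "invalid or missing bearer token"}).encode()]
        qs = parse_qs(environ.get("QUERY_STRING", ""), keep_blank_values=True)
        params = {k: v[0] for k, v in qs.items()}
        status, body = handle_get(params, corpus, w, log=log)
        if isinstance(body, str):
            payload = body.encode("utf-8")
            ctype = "text/plain; charset=utf-8"
        else:
            payload = json.dumps(body, ensure_ascii=False).encode("utf-8")
            ctype = "application/json"
        start_response(_STATUS_LINES[status], [("Content-Type", ctype)])
        return [payload]

    return app


def serve(config: ServiceConfig, host: str = "127.0.0.1", port: int = 8000) -> None:
    """Run the endpoint with wsgiref's reference server (blocking)."""
    corpus = load_corpus_jsonl(config.corpus_path)
    w = DEFAULT_WEIGHTS
    if config.weights_path:
        with open(config.weights_path, encoding="utf-8") as fh:
            w = tuple(json.load(fh)["weights"])
    log = QueryLog(config.log_path)
    app = make_wsgi_app(corpus, w, log=log, token=config.token)
    with make_server(host, port, app) as httpd:
        httpd.serve_forever()
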