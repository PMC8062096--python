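"""Readers and writers for BLAST result documents.

Two dialects are supported:

* the NCBI BLAST XML report (``-outfmt 5``, DTD ``NCBI_BlastOutput``), read
  and written losslessly;
* the tabular report (``-outfmt 6/7``) with an extended column map —
  the conventional 12 columns plus identities, gaps, raw score and
  query/subject lengths — declared in the ``# Fields:`` comment line.
  The commented variant (outfmt 7) additionally carries the per-query
  statistics block and search parameters in comment lines so that a
  result round-trips through it; the bare variant (outfmt 6) is lossy by
  construction (no statistics block, zero-hit queries absent).

E-values are transported as decimal strings derived from their natural
logarithm, so values below the double-precision floor never collapse to
0.0 in a written document; a parsed literal ``0.0`` is flagged as
zero-rounded and later regenerated from its raw score rather than rescaled.
Gzip-compressed inputs are accepted transparently.
"""

from __future__ import annotations

import gzip
import io as _io
import math
from pathlib import Path
from typing import List, Optional, Sequence, Union

from lxml import etree

from .model import (
    Hit,
    Hsp,
    SearchParams,
    SearchResult,
    StatisticsBlock,
)
from .stats import (
    DatabaseProfile,
    EValue,
    QueryProfile,
    format_evalue,
    parse_evalue,
)

__all__ = ["ParseError", "CapabilityError", "parse_result", "write_result"]


class ParseError(ValueError):
    """A result document could not be parsed; message carries the location."""


class CapabilityError(RuntimeError):
    """The input lacks information a downstream operation requires."""


_TABULAR_FIELDS = (
    "query id",
    "subject id",
    "% identity",
    "alignment length",
    "identities",
    "gaps",
    "q. start",
    "q. end",
    "s. start",
    "s. end",
    "evalue",
    "bit score",
    "score",
    "query length",
    "subject length",
)

_MOLECULE_BY_PROGRAM = {
    # molecule type of the database each program searches
    "blastn": "nucleotide",
    "tblastx": "nucleotide",
    "tblastn": "nucleotide",
    "blastp": "protein",
    "blastx": "protein",
}


def _open_text(source) -> _io.TextIOBase:
    if hasattr(source, "read"):
        data = source.read()
        if isinstance(data, str):
            return _io.StringIO(data)
        raw = data
    else:
        raw = Path(source).read_bytes()
    if raw[:2] == b"\x1f\x8b":
        raw = gzip.decompress(raw)
    return _io.StringIO(raw.decode("utf-8"))


def parse_result(source, dialect: str = "xml") -> List[SearchResult]:
    """Parse a result document into one :class:`SearchResult` per query.

    ``source`` is a path or an open stream; gzip input is detected by magic
    bytes.  ``dialect`` is ``"xml"`` (outfmt 5) or ``"tabular"``
    (outfmt 6/7, comment lines auto-detected).
    """
    stream = _open_text(source)
    if dialect == "xml":
        return _parse_xml(stream)
    if dialect == "tabular":
        return _parse_tabular(stream)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_result(
    results: Union[SearchResult, Sequence[SearchResult]],
    dialect: str = "xml",
    *,
    path=None,
    with_comments: bool = True,
    report_limit: Optional[int] = None,
) -> str:
    """Serialize one or more results (same program/database) to a document.

    ``with_comments`` selects outfmt 7 over outfmt 6 for the tabular dialect.
    ``report_limit`` truncates each query's hit list in the written document
    (e.g. to ``max_target_seqs`` for NCBI-compatible output) without touching
    the in-memory result, which retains its fuller stored list.
    """
    if isinstance(results, SearchResult):
        results = [results]
    if not results:
        raise ValueError("nothing to write")
    if dialect == "xml":
        text = _write_xml(results, report_limit)
    elif dialect == "tabular":
        text = _write_tabular(results, with_comments, report_limit)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


# ---------------------------------------------------------------------------
# XML dialect
# ---------------------------------------------------------------------------

_XML_DOCTYPE = (
    '<!DOCTYPE BlastOutput PUBLIC "-//NCBI//NCBI BlastOutput/EN" '
    '"http://www.ncbi.nlm.nih.gov/dtd/NCBI_BlastOutput.dtd">'
)


def _sub(parent, tag: str, text=None):
    el = etree.SubElement(parent, tag)
    if text is not None:
        el.text = str(text)
    return el


def _fmt_float(x: float) -> str:
    return repr(float(x))


def _write_xml(results: Sequence[SearchResult], report_limit: Optional[int]) -> str:
    first = results[0]
    root = etree.Element("BlastOutput")
    _sub(root, "BlastOutput_program", first.program)
    _sub(root, "BlastOutput_version", f"{first.program.upper()} (incblast)")
    _sub(root, "BlastOutput_reference", "incblast serialized search result")
    _sub(root, "BlastOutput_db", first.db.db_id)
    _sub(root, "BlastOutput_query-ID", "Query_1")
    _sub(root, "BlastOutput_query-def", first.query.query_id)
    _sub(root, "BlastOutput_query-len", first.query.m)
    param_el = _sub(root, "BlastOutput_param")
    p = _sub(param_el, "Parameters")
    if first.params.matrix is not None:
        _sub(p, "Parameters_matrix", first.params.matrix)
    _sub(p, "Parameters_expect", _fmt_float(first.params.expect))
    if first.params.match is not None:
        _sub(p, "Parameters_sc-match", first.params.match)
    if first.params.mismatch is not None:
        _sub(p, "Parameters_sc-mismatch", first.params.mismatch)
    _sub(p, "Parameters_gap-open", first.params.gap_open)
    _sub(p, "Parameters_gap-extend", first.params.gap_extend)
    # not part of the NCBI DTD, carried as a comment so documents stay valid
    p.append(etree.Comment(f"incblast:max-target-seqs={first.params.max_target_seqs}"))
    iterations = _sub(root, "BlastOutput_iterations")
    for i, result in enumerate(results, start=1):
        it = _sub(iterations, "Iteration")
        _sub(it, "Iteration_iter-num", i)
        _sub(it, "Iteration_query-ID", f"Query_{i}")
        _sub(it, "Iteration_query-def", result.query.query_id)
        _sub(it, "Iteration_query-len", result.query.m)
        hits_el = _sub(it, "Iteration_hits")
        hits = result.hits
        if report_limit is not None:
            hits = hits[:report_limit]
        for hn, hit in enumerate(hits, start=1):
            hit_el = _sub(hits_el, "Hit")
            _sub(hit_el, "Hit_num", hn)
            _sub(hit_el, "Hit_id", hit.subject_id)
            _sub(hit_el, "Hit_def", hit.subject_def)
            _sub(hit_el, "Hit_accession", hit.subject_id)
            _sub(hit_el, "Hit_len", hit.subject_len)
            hsps_el = _sub(hit_el, "Hit_hsps")
            for pn, hsp in enumerate(hit.hsps, start=1):
                h = _sub(hsps_el, "Hsp")
                _sub(h, "Hsp_num", pn)
                _sub(h, "Hsp_bit-score", f"{hsp.bit_score:.4f}")
                if hsp.raw_score is not None:
                    _sub(h, "Hsp_score", hsp.raw_score)
                _sub(h, "Hsp_evalue", format_evalue(hsp.evalue))
                _sub(h, "Hsp_query-from", hsp.q_start)
                _sub(h, "Hsp_query-to", hsp.q_end)
                _sub(h, "Hsp_hit-from", hsp.s_start)
                _sub(h, "Hsp_hit-to", hsp.s_end)
                # frames default to 1/1 for nucleotide programs (plus strand)
                nucl = result.program in ("blastn", "tblastx")
                q_frame = hsp.q_frame if hsp.q_frame is not None else (1 if nucl else None)
                s_frame = hsp.s_frame if hsp.s_frame is not None else (1 if nucl else None)
                if q_frame is not None:
                    _sub(h, "Hsp_query-frame", q_frame)
                if s_frame is not None:
                    _sub(h, "Hsp_hit-frame", s_frame)
                _sub(h, "Hsp_identity", hsp.identity)
                if hsp.positive is not None:
                    _sub(h, "Hsp_positive", hsp.positive)
                _sub(h, "Hsp_gaps", hsp.gaps)
                _sub(h, "Hsp_align-len", hsp.align_len)
                if hsp.qseq is not None:
                    _sub(h, "Hsp_qseq", hsp.qseq)
                if hsp.hseq is not None:
                    _sub(h, "Hsp_hseq", hsp.hseq)
                if hsp.midline is not None:
                    _sub(h, "Hsp_midline", hsp.midline)
        stat_el = _sub(it, "Iteration_stat")
        s = _sub(stat_el, "Statistics")
        st = result.stats
        _sub(s, "Statistics_db-num", st.db_num if st.db_num is not None else 0)
        _sub(s, "Statistics_db-len", st.db_len if st.db_len is not None else 0)
        _sub(s, "Statistics_hsp-len", st.hsp_len if st.hsp_len is not None else 0)
        _sub(s, "Statistics_eff-space", st.eff_space if st.eff_space is not None else 0)
        _sub(s, "Statistics_kappa", _fmt_float(st.kappa) if st.kappa is not None else 0)
        _sub(
            s,
            "Statistics_lambda",
            _fmt_float(st.lambda_) if st.lambda_ is not None else 0,
        )
        _sub(
            s,
            "Statistics_entropy",
            _fmt_float(st.entropy) if st.entropy is not None else 0,
        )
    body = etree.tostring(root, pretty_print=True, encoding="unicode")
    return f'<?xml version="1.0"?>\n{_XML_DOCTYPE}\n{body}'


def _text(el, tag: str, default=None):
    found = el.findtext(tag)
    return found if found is not None else default


def _opt_int(value) -> Optional[int]:
    return None if value is None else int(float(value))


def _opt_float(value) -> Optional[float]:
    return None if value is None else float(value)


def _parse_xml(stream) -> List[SearchResult]:
    try:
        tree = etree.parse(_io.BytesIO(stream.read().encode("utf-8")))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed BLAST XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != "BlastOutput":
        raise ParseError(f"not a BLAST XML document (root element {root.tag!r})")
    program = _text(root, "BlastOutput_program")
    if program is None:
        raise ParseError("missing BlastOutput_program")
    db_id = _text(root, "BlastOutput_db", "")
    top_query_def = _text(root, "BlastOutput_query-def")
    top_query_len = _opt_int(_text(root, "BlastOutput_query-len"))
    params = _parse_xml_params(root)
    molecule = _MOLECULE_BY_PROGRAM.get(program, "nucleotide")

    results: List[SearchResult] = []
    for it in root.findall("BlastOutput_iterations/Iteration"):
        qdef = _text(it, "Iteration_query-def", top_query_def)
        qlen = _opt_int(_text(it, "Iteration_query-len"))
        if qlen is None:
            qlen = top_query_len
        if qdef is None or qlen is None:
            raise ParseError("iteration missing query definition or length")
        stats = _parse_xml_stats(it)
        hits = [_parse_xml_hit(h) for h in it.findall("Iteration_hits/Hit")]
        db = DatabaseProfile(
            db_id=db_id,
            n=stats.db_len or 0,
            N=stats.db_num or 0,
            molecule=molecule,
        )
        results.append(
            SearchResult(
                program=program,
                query=QueryProfile(query_id=qdef, m=qlen),
                db=db,
                params=params,
                hits=hits,
                stats=stats,
            )
        )
    if not results:
        raise ParseError("document contains no query iterations")
    return results


def _parse_xml_params(root) -> SearchParams:
    p = root.find("BlastOutput_param/Parameters")
    mts = 500
    if p is None:
        return SearchParams()
    for node in p.iter(etree.Comment):
        text = (node.text or "").strip()
        if text.startswith("incblast:max-target-seqs="):
            mts = int(text.split("=", 1)[1])
    return SearchParams(
        max_target_seqs=mts,
        expect=float(_text(p, "Parameters_expect", 10.0)),
        matrix=_text(p, "Parameters_matrix"),
        match=_opt_int(_text(p, "Parameters_sc-match")),
        mismatch=_opt_int(_text(p, "Parameters_sc-mismatch")),
        gap_open=int(_text(p, "Parameters_gap-open", 0)),
        gap_extend=int(_text(p, "Parameters_gap-extend", 0)),
    )


def _parse_xml_stats(it) -> StatisticsBlock:
    s = it.find("Iteration_stat/Statistics")
    if s is None:
        return StatisticsBlock()
    return StatisticsBlock(
        db_num=_opt_int(_text(s, "Statistics_db-num")),
        db_len=_opt_int(_text(s, "Statistics_db-len")),
        hsp_len=_opt_int(_text(s, "Statistics_hsp-len")),
        eff_space=_opt_int(_text(s, "Statistics_eff-space")),
        kappa=_opt_float(_text(s, "Statistics_kappa")),
        lambda_=_opt_float(_text(s, "Statistics_lambda")),
        entropy=_opt_float(_text(s, "Statistics_entropy")),
    )


def _parse_xml_hit(h) -> Hit:
    subject_id = _text(h, "Hit_id", "")
    subject_def = _text(h, "Hit_def", subject_id)
    hsps = []
    for x in h.findall("Hit_hsps/Hsp"):
        ev_text = _text(x, "Hsp_evalue")
        if ev_text is None:
            raise ParseError(f"HSP of hit {subject_id!r} missing Hsp_evalue")
        hsps.append(
            Hsp(
                raw_score=_opt_int(_text(x, "Hsp_score")),
                bit_score=float(_text(x, "Hsp_bit-score", 0.0)),
                evalue=parse_evalue(ev_text),
                q_start=int(_text(x, "Hsp_query-from", 0)),
                q_end=int(_text(x, "Hsp_query-to", 0)),
                s_start=int(_text(x, "Hsp_hit-from", 0)),
                s_end=int(_text(x, "Hsp_hit-to", 0)),
                identity=int(_text(x, "Hsp_identity", 0)),
                align_len=int(_text(x, "Hsp_align-len", 0)),
                gaps=int(_text(x, "Hsp_gaps", 0)),
                positive=_opt_int(_text(x, "Hsp_positive")),
                q_frame=_opt_int(_text(x, "Hsp_query-frame")),
                s_frame=_opt_int(_text(x, "Hsp_hit-frame")),
                qseq=_text(x, "Hsp_qseq"),
                hseq=_text(x, "Hsp_hseq"),
                midline=_text(x, "Hsp_midline"),
            )
        )
    return Hit(
        subject_id=subject_id,
        subject_def=subject_def,
        subject_len=int(_text(h, "Hit_len", 0)),
        hsps=hsps,
    )


# ---------------------------------------------------------------------------
# Tabular dialect (outfmt 6/7)
# ---------------------------------------------------------------------------


def _params_comment(params: SearchParams) -> str:
    parts = [
        f"max-target-seqs={params.max_target_seqs}",
        f"expect={params.expect!r}",
        f"matrix={params.matrix if params.matrix is not None else '.'}",
        f"match={params.match if params.match is not None else '.'}",
        f"mismatch={params.mismatch if params.mismatch is not None else '.'}",
        f"gap-open={params.gap_open}",
        f"gap-extend={params.gap_extend}",
    ]
    return ";".join(parts)


def _stats_comment(st: StatisticsBlock) -> str:
    def fmt(v):
        return "." if v is None else (repr(v) if isinstance(v, float) else str(v))

    return ";".join(
        [
            f"db-num={fmt(st.db_num)}",
            f"db-len={fmt(st.db_len)}",
            f"hsp-len={fmt(st.hsp_len)}",
            f"eff-space={fmt(st.eff_space)}",
            f"kappa={fmt(st.kappa)}",
            f"lambda={fmt(st.lambda_)}",
            f"entropy={fmt(st.entropy)}",
        ]
    )


def _write_tabular(
    results: Sequence[SearchResult], with_comments: bool, report_limit: Optional[int]
) -> str:
    lines: List[str] = []
    for result in results:
        hits = result.hits
        if report_limit is not None:
            hits = hits[:report_limit]
        n_rows = sum(len(h.hsps) for h in hits)
        if with_comments:
            lines.append(f"# {result.program}")
            lines.append(f"# Query: {result.query.query_id}")
            lines.append(f"# Query-len: {result.query.m}")
            lines.append(f"# Database: {result.db.db_id}")
            lines.append(f"# Fields: {', '.join(_TABULAR_FIELDS)}")
            lines.append(f"# Params: {_params_comment(result.params)}")
            lines.append(f"# Statistics: {_stats_comment(result.stats)}")
            lines.append(f"# {n_rows} hits found")
        for hit in hits:
            for hsp in hit.hsps:
                pident = 100.0 * hsp.identity / hsp.align_len if hsp.align_len else 0.0
                lines.append(
                    "\t".join(
                        (
                            result.query.query_id,
                            hit.subject_id,
                            f"{pident:.3f}",
                            str(hsp.align_len),
                            str(hsp.identity),
                            str(hsp.gaps),
                            str(hsp.q_start),
                            str(hsp.q_end),
                            str(hsp.s_start),
                            str(hsp.s_end),
                            format_evalue(hsp.evalue),
                            f"{hsp.bit_score:.4f}",
                            str(hsp.raw_score) if hsp.raw_score is not None else ".",
                            str(result.query.m),
                            str(hit.subject_len),
                        )
                    )
                )
    return "\n".join(lines) + "\n"


def _parse_kv_comment(payload: str) -> dict:
    out = {}
    for item in payload.split(";"):
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def _maybe(value: str, conv):
    return None if value in (".", "", None) else conv(value)


def _parse_tabular(stream) -> List[SearchResult]:
    results: List[SearchResult] = []
    current: Optional[dict] = None  # per-query parse state

    def flush():
        nonlocal current
        if current is None or current["query_id"] is None:
            return
        hits: List[Hit] = []
        for sid in current["hit_order"]:
            rows = current["hits"][sid]
            hits.append(
                Hit(
                    subject_id=sid,
                    subject_def=sid,
                    subject_len=rows[0]["slen"],
                    hsps=[r["hsp"] for r in rows],
                )
            )
        stats = current["stats"]
        params = current["params"]
        molecule = _MOLECULE_BY_PROGRAM.get(current["program"] or "blastn", "nucleotide")
        results.append(
            SearchResult(
                program=current["program"] or "blastn",
                query=QueryProfile(
                    query_id=current["query_id"], m=current["query_len"] or 1
                ),
                db=DatabaseProfile(
                    db_id=current["db_id"],
                    n=stats.db_len or 0,
                    N=stats.db_num or 0,
                    molecule=molecule,
                ),
                params=params,
                hits=hits,
                stats=stats,
            )
        )
        current = None

    def fresh() -> dict:
        return {
            "program": None,
            "query_id": None,
            "query_len": None,
            "db_id": "",
            "stats": StatisticsBlock(),
            "params": SearchParams(),
            "hits": {},
            "hit_order": [],
        }

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.split(" ")[0].lower() in _MOLECULE_BY_PROGRAM:
                # a program line starts a new per-query block
                flush()
                current = fresh()
                current["program"] = body.split(" ")[0].lower()
                continue
            if body.startswith("Query:"):
                if current is not None and current["query_id"] is not None:
                    flush()
                if current is None:
                    current = fresh()
                current["query_id"] = body.split(":", 1)[1].strip()
            elif current is None:
                current = fresh()
            if body.startswith("Query-len:"):
                current["query_len"] = int(body.split(":", 1)[1])
            elif body.startswith("Database:"):
                current["db_id"] = body.split(":", 1)[1].strip()
            elif body.startswith("Statistics:"):
                kv = _parse_kv_comment(body.split(":", 1)[1])
                current["stats"] = StatisticsBlock(
                    db_num=_maybe(kv.get("db-num"), int),
                    db_len=_maybe(kv.get("db-len"), int),
                    hsp_len=_maybe(kv.get("hsp-len"), int),
                    eff_space=_maybe(kv.get("eff-space"), int),
                    kappa=_maybe(kv.get("kappa"), float),
                    lambda_=_maybe(kv.get("lambda"), float),
                    entropy=_maybe(kv.get("entropy"), float),
                )
            elif body.startswith("Params:"):
                kv = _parse_kv_comment(body.split(":", 1)[1])
                current["params"] = SearchParams(
                    max_target_seqs=int(kv.get("max-target-seqs", 500)),
                    expect=float(kv.get("expect", 10.0)),
                    matrix=_maybe(kv.get("matrix"), str),
                    match=_maybe(kv.get("match"), int),
                    mismatch=_maybe(kv.get("mismatch"), int),
                    gap_open=int(kv.get("gap-open", 0)),
                    gap_extend=int(kv.get("gap-extend", 0)),
                )
            continue
        cols = line.split("\t")
        if len(cols) < 12:
            raise ParseError(
                f"line {lineno}: expected >= 12 tab-separated columns, got {len(cols)}"
            )
        if current is None:
            current = fresh()
        qid = cols[0]
        if current["query_id"] is None:
            current["query_id"] = qid
        elif current["query_id"] != qid:
            flush()
            current = fresh()
            current["query_id"] = qid
        try:
            hsp = Hsp(
                raw_score=_maybe(cols[12], int) if len(cols) > 12 else None,
                bit_score=float(cols[11]),
                evalue=parse_evalue(cols[10]),
                q_start=int(cols[6]),
                q_end=int(cols[7]),
                s_start=int(cols[8]),
                s_end=int(cols[9]),
                identity=int(cols[4]),
                align_len=int(cols[3]),
                gaps=int(cols[5]),
            )
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
        if len(cols) > 13:
            current["query_len"] = int(cols[13])
        slen = int(cols[14]) if len(cols) > 14 else 0
        sid = cols[1]
        if sid not in current["hits"]:
            current["hits"][sid] = []
            current["hit_order"].append(sid)
        current["hits"][sid].append({"hsp": hsp, "slen": slen})
    flush()
    return results


def require_raw_scores(result: SearchResult) -> None:
    """Raise :class:`CapabilityError` if any HSP lacks a raw score.

    Karlin-Altschul recalibration recomputes e-values from raw scores; a
    tabular input written without the score column cannot take that path.
    """
    for hit in result.hits:
        for hsp in hit.hsps:
            if hsp.raw_score is None:
                raise CapabilityError(
                    f"hit {hit.subject_id!r} has an HSP without a raw score; "
                    "Karlin-Altschul correction needs the score column"
                )
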