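"""JSON query service over a released bundle.

A read-only, stateless WSGI application exposing the released counts and
association measures over HTTP GET, grouped into four resources:

* ``/metadata/datasets``, ``/metadata/domainCounts``,
  ``/metadata/domainPairCounts``, ``/metadata/patientCount``
* ``/omop/findConceptIDs``, ``/omop/concepts``
* ``/frequencies/singleConceptFreq``, ``/frequencies/pairedConceptFreq``,
  ``/frequencies/mostFrequentConcepts``,
  ``/frequencies/associatedConceptFreq``,
  ``/frequencies/associatedConceptDomainFreq``
* ``/association/chiSquare``, ``/association/obsExpRatio``,
  ``/association/relativeFrequency``

Every endpoint is a thin JSON view over the library: the numeric payload
equals the corresponding library call exactly.  A concept id absent from
a released table yields empty ``results`` — by construction the service
cannot distinguish "never observed" from "excluded for privacy", and it
makes no such claim.  Vocabulary-mapping endpoints respond with a
structured "vocabulary not loaded" notice unless a concept-relationship
extract were provided (none is required here).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict
from typing import Any, Callable
from urllib.parse import parse_qs

from ehrfreq.associations import (
    associate,
    most_frequent,
    relative_frequency,
    top_associated,
)
from ehrfreq.cohd_files import CohdBundle, DatasetTables
from ehrfreq.errors import EhrFreqError, NotFoundError


class ServiceError(EhrFreqError):
    def __init__(self, message: str, status: int = 400):
        super().__init__(message)
        self.status = status


def _clean(value: Any) -> Any:
    """JSON-safe copy: NaN/inf become None."""
    if isinstance(value, float) and not math.isfinite(value):
        return None
    if isinstance(value, dict):
        return {k: _clean(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_clean(v) for v in value]
    return value


class QueryService:
    """Endpoint logic over one loaded bundle; all methods return plain dicts."""

    def __init__(self, bundle: CohdBundle):
        self.bundle = bundle

    # -- helpers ---------------------------------------------------------

    def _dataset(self, dataset_id: str | None) -> DatasetTables:
        datasets = self.bundle.datasets
        if not datasets:
            raise ServiceError("no datasets loaded", status=500)
        if dataset_id is None:
            dataset_id = sorted(datasets)[0]
        if dataset_id not in datasets:
            raise ServiceError(f"unknown dataset {dataset_id!r}", status=404)
        return datasets[dataset_id]

    def _domain(self, concept_id: int) -> str:
        concept = self.bundle.concepts.get(concept_id)
        return concept.domain_id if concept else ""

    def _single_count(self, tables: DatasetTables, concept_id: int) -> float | None:
        rows = tables.singles[tables.singles["concept_id"] == concept_id]
        return float(rows["count"].iloc[0]) if len(rows) else None

    def _pair_count(self, tables: DatasetTables, c1: int, c2: int) -> float | None:
        lo, hi = min(c1, c2), max(c1, c2)
        rows = tables.pairs[
            (tables.pairs["concept_id_1"] == lo) & (tables.pairs["concept_id_2"] == hi)
        ]
        return float(rows["count"].iloc[0]) if len(rows) else None

    # -- metadata --------------------------------------------------------

    def datasets(self) -> dict:
        results = [
            {
                "dataset_id": ds.metadata.dataset_id,
                "date_window": [str(d) for d in ds.metadata.date_window]
                if ds.metadata.date_window else None,
                "patient_count": ds.metadata.patient_count,
            }
            for _, ds in sorted(self.bundle.datasets.items())
        ]
        return {"results": results}

    def domain_counts(self, dataset_id: str | None = None) -> dict:
        tables = self._dataset(dataset_id)
        tally: dict[str, int] = {}
        for cid in tables.singles["concept_id"]:
            tally[self._domain(int(cid))] = tally.get(self._domain(int(cid)), 0) + 1
        results = [
            {"dataset_id": tables.metadata.dataset_id, "domain_id": d, "count": n}
            for d, n in sorted(tally.items())
        ]
        return {"results": results}

    def domain_pair_counts(self, dataset_id: str | None = None) -> dict:
        tables = self._dataset(dataset_id)
        tally: dict[tuple[str, str], int] = {}
        for c1, c2 in zip(tables.pairs["concept_id_1"], tables.pairs["concept_id_2"]):
            pair = tuple(sorted((self._domain(int(c1)), self._domain(int(c2)))))
            tally[pair] = tally.get(pair, 0) + 1
        results = [
            {
                "dataset_id": tables.metadata.dataset_id,
                "domain_id_1": d1,
                "domain_id_2": d2,
                "count": n,
            }
            for (d1, d2), n in sorted(tally.items())
        ]
        return {"results": results}

    def patient_count(self, dataset_id: str | None = None) -> dict:
        tables = self._dataset(dataset_id)
        return {
            "results": [
                {
                    "dataset_id": tables.metadata.dataset_id,
                    "count": tables.metadata.patient_count,
                }
            ]
        }

    # -- omop ------------------------------------------------------------

    def find_concepts(self, query: str, domain: str | None = None) -> dict:
        if not query:
            raise ServiceError("query string must be non-empty")
        needle = query.lower()
        matches = [
            c
            for c in self.bundle.concepts.values()
            if needle in c.concept_name.lower()
            and (domain is None or c.domain_id == domain)
        ]
        matches.sort(
            key=lambda c: (
                c.concept_name.lower() != needle,  # exact matches first
                len(c.concept_name),
                c.concept_id,
            )
        )
        return {"results": [_clean(asdict(c)) for c in matches]}

    def concept_definitions(self, concept_ids: list[int]) -> dict:
        results = [
            asdict(self.bundle.concepts[cid])
            for cid in concept_ids
            if cid in self.bundle.concepts
        ]
        return {"results": results}

    def map_vocabulary(self, **_params) -> dict:
        return {
            "results": [],
            "notice": "vocabulary not loaded: concept-relationship extract required",
        }

    # -- frequencies -----------------------------------------------------

    def single_concept_freq(self, concept_id: int, dataset_id: str | None = None) -> dict:
        tables = self._dataset(dataset_id)
        count = self._single_count(tables, concept_id)
        if count is None:
            return {"results": [], "notice": "concept not present in released counts"}
        n_p = tables.metadata.patient_count
        return {
            "results": [
                {
                    "dataset_id": tables.metadata.dataset_id,
                    "concept_id": concept_id,
                    "concept_count": count,
                    "concept_frequency": count / n_p if n_p else None,
                }
            ]
        }

    def paired_concept_freq(
        self, concept_id_1: int, concept_id_2: int, dataset_id: str | None = None
    ) -> dict:
        tables = self._dataset(dataset_id)
        count = self._pair_count(tables, concept_id_1, concept_id_2)
        if count is None:
            return {"results": [], "notice": "pair not present in released counts"}
        n_p = tables.metadata.patient_count
        return {
            "results": [
                {
                    "dataset_id": tables.metadata.dataset_id,
                    "concept_id_1": concept_id_1,
                    "concept_id_2": concept_id_2,
                    "concept_count": count,
                    "concept_frequency": count / n_p if n_p else None,
                }
            ]
        }

    def most_frequent_concepts(
        self, k: int = 10, domain: str | None = None, dataset_id: str | None = None
    ) -> dict:
        tables = self._dataset(dataset_id)
        try:
            frame = most_frequent(tables.singles, self.bundle.concepts, domain=domain, k=k)
        except NotFoundError as exc:
            raise ServiceError(str(exc), status=404) from exc
        records = frame.to_dict(orient="records")
        for record in records:
            record["dataset_id"] = tables.metadata.dataset_id
        return {"results": _clean(records)}

    def associated_concept_freq(
        self,
        concept_id: int,
        domain: str | None = None,
        metric: str = "count",
        k: int = 10,
        dataset_id: str | None = None,
    ) -> dict:
        tables = self._dataset(dataset_id)
        try:
            results = top_associated(
                tables.pairs,
                tables.singles,
                anchor=concept_id,
                n_p=tables.metadata.patient_count,
                concepts=self.bundle.concepts,
                domain=domain,
                metric=metric,
                k=k,
            )
        except NotFoundError:
            return {"results": [], "notice": "concept not present in released counts"}
        records = []
        for result in results:
            record = _clean(asdict(result))
            record["dataset_id"] = tables.metadata.dataset_id
            records.append(record)
        return {"results": records}

    # -- association -----------------------------------------------------

    def _pair_inputs(
        self, concept_id_1: int, concept_id_2: int, dataset_id: str | None
    ) -> tuple[DatasetTables, float, float, float] | dict:
        tables = self._dataset(dataset_id)
        n12 = self._pair_count(tables, concept_id_1, concept_id_2)
        n1 = self._single_count(tables, concept_id_1)
        n2 = self._single_count(tables, concept_id_2)
        if n12 is None or n1 is None or n2 is None:
            return {"results": [], "notice": "concept or pair not present in released counts"}
        return tables, n12, n1, n2

    def chi_square_endpoint(
        self, concept_id_1: int, concept_id_2: int, dataset_id: str | None = None
    ) -> dict:
        found = self._pair_inputs(concept_id_1, concept_id_2, dataset_id)
        if isinstance(found, dict):
            return found
        tables, n12, n1, n2 = found
        try:
            result = associate(
                n12, n1, n2, tables.metadata.patient_count, concept_id_1, concept_id_2
            )
        except EhrFreqError as exc:
            return {"results": [], "error": str(exc)}
        return {
            "results": [
                {
                    "dataset_id": tables.metadata.dataset_id,
                    "concept_id_1": concept_id_1,
                    "concept_id_2": concept_id_2,
                    "chi_square": result.chi2,
                    "p_value": result.p_value,
                }
            ]
        }

    def obs_exp_ratio(
        self, concept_id_1: int, concept_id_2: int, dataset_id: str | None = None
    ) -> dict:
        found = self._pair_inputs(concept_id_1, concept_id_2, dataset_id)
        if isinstance(found, dict):
            return found
        tables, n12, n1, n2 = found
        n_p = tables.metadata.patient_count
        expected = n1 * n2 / n_p if n_p else None
        ln_ratio = math.log(n12 / expected) if expected and n12 > 0 else None
        return {
            "results": [
                {
                    "dataset_id": tables.metadata.dataset_id,
                    "concept_id_1": concept_id_1,
                    "concept_id_2": concept_id_2,
                    "observed_count": n12,
                    "expected_count": expected,
                    "ln_ratio": ln_ratio,
                }
            ]
        }

    def relative_frequency_endpoint(
        self, concept_id_1: int, concept_id_2: int, dataset_id: str | None = None
    ) -> dict:
        """FR(C1|C2): pair count divided by the base concept (C2) count."""
        found = self._pair_inputs(concept_id_1, concept_id_2, dataset_id)
        if isinstance(found, dict):
            return found
        tables, n12, _n1, n2 = found
        return {
            "results": [
                {
                    "dataset_id": tables.metadata.dataset_id,
                    "concept_id": concept_id_1,
                    "concept_2_id": concept_id_2,
                    "concept_pair_count": n12,
                    "concept_2_count": n2,
                    "relative_frequency": relative_frequency(n12, n2),
                }
            ]
        }


# -- WSGI layer ----------------------------------------------------------


def _param(params: dict, name: str, cast: Callable = str, default=None, required=False):
    if name not in params:
        if required:
            raise ServiceError(f"missing required parameter {name!r}")
        return default
    try:
        return cast(params[name][0])
    except (TypeError, ValueError) as exc:
        raise ServiceError(f"invalid value for parameter {name!r}") from exc


def create_app(bundle: CohdBundle):
    """Build the WSGI application serving ``bundle``."""
    service = QueryService(bundle)

    def handle(path: str, params: dict) -> dict:
        dataset_id = _param(params, "dataset_id")
        if path == "/metadata/datasets":
            return service.datasets()
        if path == "/metadata/domainCounts":
            return service.domain_counts(dataset_id)
        if path == "/metadata/domainPairCounts":
            return service.domain_pair_counts(dataset_id)
        if path == "/metadata/patientCount":
            return service.patient_count(dataset_id)
        if path == "/omop/findConceptIDs":
            return service.find_concepts(
                _param(params, "q", required=True), _param(params, "domain")
            )
        if path == "/omop/concepts":
            raw = _param(params, "concept_ids", required=True)
            return service.concept_definitions([int(v) for v in raw.split(",") if v])
        if path in ("/omop/mapFromStandardConceptID", "/omop/mapToStandardConceptID",
                    "/omop/vocabularies"):
            return service.map_vocabulary()
        if path == "/frequencies/singleConceptFreq":
            return service.single_concept_freq(
                _param(params, "concept_id", int, required=True), dataset_id
            )
        if path == "/frequencies/pairedConceptFreq":
            return service.paired_concept_freq(
                _param(params, "concept_id_1", int, required=True),
                _param(params, "concept_id_2", int, required=True),
                dataset_id,
            )
        if path == "/frequencies/mostFrequentConcepts":
            return service.most_frequent_concepts(
                k=_param(params, "k", int, default=10),
                domain=_param(params, "domain"),
                dataset_id=dataset_id,
            )
        if path in ("/frequencies/associatedConceptFreq",
                    "/frequencies/associatedConceptDomainFreq"):
            return service.associated_concept_freq(
                _param(params, "concept_id", int, required=True),
                domain=_param(params, "domain"),
                metric=_param(params, "metric", default="count"),
                k=_param(params, "k", int, default=10),
                dataset_id=dataset_id,
            )
        if path == "/association/chiSquare":
            return service.chi_square_endpoint(
                _param(params, "concept_id_1", int, required=True),
                _param(params, "concept_id_2", int, required=True),
                dataset_id,
            )
        if path == "/association/obsExpRatio":
            return service.obs_exp_ratio(
                _param(params, "concept_id_1", int, required=True),
                _param(params, "concept_id_2", int, required=True),
                dataset_id,
            )
        if path == "/association/relativeFrequency":
            return service.relative_frequency_endpoint(
                _param(params, "concept_id_1", int, required=True),
                _param(params, "concept_id_2", int, required=True),
                dataset_id,
            )
        raise ServiceError(f"unknown endpoint {path!r}", status=404)

    def app(environ, start_response):
        path = environ.get("PATH_INFO", "/")
        params = parse_qs(environ.get("QUERY_STRING", ""))
        try:
            payload = handle(path, params)
            status = "200 OK"
        except ServiceError as exc:
            payload = {"results": [], "error": str(exc)}
            status = {400: "400 Bad Request", 404: "404 Not Found",
                      500: "500 Internal Server Error"}.get(exc.status, "400 Bad Request")
        body = json.dumps(_clean(payload)).encode("utf-8")
        start_response(
            status,
            [("Content-Type", "application/json"),
             ("Content-Length", str(len(body)))],
        )
        return [body]

    return app


def serve(bundle: CohdBundle, host: str = "127.0.0.1", port: int = 8080) -> None:
    """Serve a bundle with the stdlib WSGI reference server (blocking)."""
    from wsgiref.simple_server import make_server

    with make_server(host, port, create_app(bundle)) as server:
        server.serve_forever()
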