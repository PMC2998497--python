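"""End-to-end orchestration: features -> joined table -> inference report.

The unit of analysis is the protein.  Every feature (degree, clustering
coefficient, SP/DP label, coefficient of functionality, SF/DF label,
complex number, expression, Kimura distance) is joined on protein ID into
one table; each statistic then restricts itself to the complete cases for
its own variables, and the report records the n actually used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import network as net_mod
from .annotation import (
    FunctionalAnnotation,
    classify_functionality,
    functionality_coefficient,
    read_annotations,
)
from .complexes import ComplexCatalog, read_complex_catalog
from .distance import batch_distances, read_aligned_pairs
from .network import InteractionNetwork, classify_density, read_edge_list
from .stats import (
    CorrelationResult,
    GroupComparisonResult,
    PCAResult,
    RegressionResult,
    mann_whitney,
    multivariate_regression,
    partial_spearman,
    pca_determinants,
    spearman,
)
from .synthesize import SyntheticDataset

logger = logging.getLogger(__name__)

Cutoff = Union[float, Literal["mean"]]

#: the three candidate determinants correlated against evolutionary distance
DETERMINANTS = ("expression", "degree", "complex_number")


@dataclass
class AnalysisReport:
    """Structured results of the full inference chain."""

    correlations: list[CorrelationResult] = field(default_factory=list)
    partial_correlations: list[CorrelationResult] = field(default_factory=list)
    regression: Optional[RegressionResult] = None
    pca: Optional[PCAResult] = None
    pc1_distance_correlation: Optional[CorrelationResult] = None
    group_tests: dict[str, GroupComparisonResult] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def correlation(self, x_name: str, y_name: str) -> CorrelationResult:
        for c in self.correlations:
            if {c.x_name, c.y_name} == {x_name, y_name}:
                return c
        raise KeyError(f"no correlation for ({x_name}, {y_name})")

    def partial_correlation(self, x_name: str, y_name: str) -> CorrelationResult:
        for c in self.partial_correlations:
            if {c.x_name, c.y_name} == {x_name, y_name}:
                return c
        raise KeyError(f"no partial correlation for ({x_name}, {y_name})")

    def to_dict(self) -> dict:
        def corr(c: CorrelationResult) -> dict:
            return dataclasses.asdict(c) | {"controls": list(c.controls)}

        out: dict = {
            "correlations": [corr(c) for c in self.correlations],
            "partial_correlations": [corr(c) for c in self.partial_correlations],
            "notes": self.notes,
        }
        if self.regression is not None:
            out["regression"] = {
                "n": self.regression.n,
                "r_squared": self.regression.r_squared,
                "intercept": self.regression.intercept,
                "predictors": [dataclasses.asdict(p) for p in self.regression.predictors],
            }
        if self.pca is not None:
            out["pca"] = {
                "variables": list(self.pca.variable_names),
                "eigenvalues": self.pca.eigenvalues.tolist(),
                "variance_fractions": self.pca.variance_fractions.tolist(),
                "retained": self.pca.retained.tolist(),
                "loadings": self.pca.loadings.tolist(),
            }
        if self.pc1_distance_correlation is not None:
            out["pc1_distance_correlation"] = corr(self.pc1_distance_correlation)
        out["group_tests"] = {
            key: dataclasses.asdict(g) for key, g in self.group_tests.items()
        }
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def assemble_features(
    net: InteractionNetwork,
    annotation: Optional[FunctionalAnnotation] = None,
    catalog: Optional[ComplexCatalog] = None,
    expression: Optional[Mapping[str, float]] = None,
    distances: Optional[Mapping[str, float]] = None,
    func_cutoff: Cutoff = "mean",
    clust_cutoff: Cutoff = "mean",
    count_unannotated_partners: bool = True,
) -> pd.DataFrame:
    """Join all per-protein features into one table (one row per network protein).

    Missing inputs leave their columns absent; missing per-protein values
    (unannotated proteins, degree < 2, no ortholog) are NaN/None and each
    downstream statistic handles its own complete cases.  Rows are sorted
    by protein ID so the output is order-independent.
    """
    proteins = sorted(net.proteins)
    table: dict[str, list] = {"degree": [net.degree(p) for p in proteins]}

    coeffs = net_mod.all_clustering_coefficients(net)
    labels = {dl.protein: dl for dl in classify_density(coeffs, cutoff=clust_cutoff)}
    table["clustering_coefficient"] = [
        np.nan if coeffs[p] is None else coeffs[p] for p in proteins
    ]
    table["density_label"] = [
        None if labels[p].label == net_mod.UNCLASSIFIED else labels[p].label
        for p in proteins
    ]

    if annotation is not None:
        results = [
            functionality_coefficient(
                net, annotation, p, count_unannotated_partners=count_unannotated_partners
            )
            for p in proteins
        ]
        classified = classify_functionality(results, cutoff=func_cutoff)
        table["functionality_coefficient"] = [
            np.nan if r.coefficient is None else r.coefficient for r in classified
        ]
        table["assigned_class"] = [r.assigned_class for r in classified]
        table["functionality_label"] = [
            None if r.label == "unclassified" else r.label for r in classified
        ]
        table["m_partners"] = [r.m for r in classified]
        table["n_same_class"] = [r.n for r in classified]

    if catalog is not None:
        counts = catalog.complex_numbers()
        table["complex_number"] = [counts.get(p, 0) for p in proteins]
        table["complex_forming"] = [counts.get(p, 0) > 0 for p in proteins]

    if expression is not None:
        table["expression"] = [
            float(expression[p]) if p in expression else np.nan for p in proteins
        ]

    if distances is not None:
        table["kimura_distance"] = [
            float(distances[p]) if p in distances else np.nan for p in proteins
        ]

    return pd.DataFrame(table, index=pd.Index(proteins, name="protein_id"))


def _complete(features: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    missing = [c for c in columns if c not in features.columns]
    if missing:
        raise KeyError(f"columns not in feature table: {missing}")
    return features.dropna(subset=list(columns))


def _group_distance_test(
    features: pd.DataFrame,
    label_column: str,
    group_a: str,
    group_b: str,
    value_column: str = "kimura_distance",
) -> Optional[GroupComparisonResult]:
    sub = features.dropna(subset=[label_column, value_column])
    a = sub.loc[sub[label_column] == group_a, value_column].to_numpy()
    b = sub.loc[sub[label_column] == group_b, value_column].to_numpy()
    if a.size == 0 or b.size == 0:
        return None
    return mann_whitney(a, b, group_names=(group_a, group_b))


def analyze(features: pd.DataFrame) -> AnalysisReport:
    """Run the correlation / partial / regression / PCA / group-test chain.

    Each analysis restricts to the complete cases of its own variables; a
    note is recorded for every analysis skipped for lack of input columns
    or observations.
    """
    report = AnalysisReport()
    has = set(features.columns)

    # --- Spearman correlations of distance with each determinant,
    #     and partials controlling the other two
    if "kimura_distance" in has:
        present = [v for v in DETERMINANTS if v in has]
        for v in present:
            sub = _complete(features, ["kimura_distance", v])
            if len(sub) >= 3:
                report.correlations.append(
                    spearman(
                        sub[v], sub["kimura_distance"], x_name=v, y_name="kimura_distance"
                    )
                )
        if len(present) == 3:
            all_vars = ["kimura_distance", *present]
            sub = _complete(features, all_vars)
            for v in present:
                others = [w for w in present if w != v]
                if len(sub) >= 5:
                    report.partial_correlations.append(
                        partial_spearman(
                            sub[v],
                            sub["kimura_distance"],
                            controls=[sub[w] for w in others],
                            x_name=v,
                            y_name="kimura_distance",
                            control_names=others,
                        )
                    )
            # regression of distance on the three determinants
            if len(sub) > len(present) + 1:
                report.regression = multivariate_regression(
                    sub["kimura_distance"],
                    {v: sub[v] for v in present},
                )
            # PCA of the determinants; PC1 vs distance
            if len(sub) >= 3:
                pca = pca_determinants(
                    sub[present].to_numpy(), variable_names=present
                )
                report.pca = pca
                report.pc1_distance_correlation = spearman(
                    pca.pc1_scores,
                    sub["kimura_distance"].to_numpy(),
                    x_name="pc1",
                    y_name="kimura_distance",
                )
        else:
            report.notes.append(
                "partial correlations / regression / PCA skipped: need expression, "
                "degree and complex_number together"
            )
    else:
        report.notes.append("distance analyses skipped: no kimura_distance column")

    # --- group comparisons on evolutionary distance
    if "kimura_distance" in has:
        if "functionality_label" in has:
            _add_group_tests(report, features, "functionality_label", "SF", "DF")
        if "density_label" in has:
            _add_group_tests(report, features, "density_label", "DP", "SP")
        if "complex_forming" in has:
            sub = features.dropna(subset=["kimura_distance"])
            for value_column in ("kimura_distance", "expression", "degree"):
                if value_column not in has:
                    continue
                sub2 = features.dropna(subset=["complex_forming", value_column])
                a = sub2.loc[sub2["complex_forming"].astype(bool), value_column]
                b = sub2.loc[~sub2["complex_forming"].astype(bool), value_column]
                if len(a) and len(b):
                    report.group_tests[
                        f"complex_vs_noncomplex_{value_column}"
                    ] = mann_whitney(
                        a.to_numpy(),
                        b.to_numpy(),
                        group_names=("complex", "non-complex"),
                    )
    return report


def _add_group_tests(
    report: AnalysisReport,
    features: pd.DataFrame,
    label_column: str,
    group_a: str,
    group_b: str,
) -> None:
    """Overall comparison plus within complex-forming / non-complex strata."""
    key = f"{group_a}_vs_{group_b}"
    overall = _group_distance_test(features, label_column, group_a, group_b)
    if overall is not None:
        report.group_tests[key] = overall
    if "complex_forming" in features.columns:
        forming = features[features["complex_forming"].fillna(False).astype(bool)]
        non = features[~features["complex_forming"].fillna(False).astype(bool)]
        for stratum, frame in (("complex", forming), ("noncomplex", non)):
            res = _group_distance_test(frame, label_column, group_a, group_b)
            if res is not None:
                report.group_tests[f"{key}_{stratum}"] = res


def run_pipeline(
    edges: Union[str, Path, InteractionNetwork],
    annotations: Union[str, Path, FunctionalAnnotation, None] = None,
    complexes: Union[str, Path, ComplexCatalog, None] = None,
    expression: Union[str, Path, Mapping[str, float], None] = None,
    alignments: Union[str, Path, Sequence, None] = None,
    func_cutoff: Cutoff = "mean",
    clust_cutoff: Cutoff = "mean",
    out_dir: Union[str, Path, None] = None,
) -> tuple[pd.DataFrame, AnalysisReport]:
    """Ingest inputs, build the feature table, and run the full analysis.

    Every input except the edge list is optional; absent inputs disable the
    analyses that need them (logged).  ``out_dir`` writes features.tsv,
    report.json and the rendered tables/*.tsv.
    """
    if isinstance(edges, InteractionNetwork):
        net = edges
    else:
        net, _ = read_edge_list(edges)

    annotation = None
    if annotations is not None:
        annotation = (
            annotations
            if isinstance(annotations, FunctionalAnnotation)
            else read_annotations(annotations)
        )
    catalog = None
    if complexes is not None:
        catalog = (
            complexes if isinstance(complexes, ComplexCatalog) else read_complex_catalog(complexes)
        )
    expr_map: Optional[Mapping[str, float]] = None
    if expression is not None:
        if isinstance(expression, (str, Path)):
            frame = pd.read_csv(expression, sep="\t", dtype={0: str})
            expr_map = dict(zip(frame.iloc[:, 0], frame.iloc[:, 1].astype(float)))
        else:
            expr_map = expression

    distances: Optional[dict[str, float]] = None
    if alignments is not None:
        pairs = (
            read_aligned_pairs(alignments)
            if isinstance(alignments, (str, Path))
            else list(alignments)
        )
        distances = {r.protein_id: r.kimura_distance for r in batch_distances(pairs)}
        if not set(distances) & net.proteins:
            raise ValueError("no overlap between network proteins and aligned pairs")
    if expr_map is not None and not set(expr_map) & net.proteins:
        raise ValueError("no overlap between network proteins and expression table")

    features = assemble_features(
        net,
        annotation=annotation,
        catalog=catalog,
        expression=expr_map,
        distances=distances,
        func_cutoff=func_cutoff,
        clust_cutoff=clust_cutoff,
    )
    report = analyze(features)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        features.to_csv(out / "features.tsv", sep="\t")
        (out / "report.json").write_text(report.to_json())
        tables_dir = out / "tables"
        tables_dir.mkdir(exist_ok=True)
        for name, text in report_tables(report).items():
            (tables_dir / f"{name}.tsv").write_text(text)
    return features, report


def run_on_dataset(
    ds: SyntheticDataset,
    use_planted_distances: bool = False,
    func_cutoff: Cutoff = "mean",
    clust_cutoff: Cutoff = "mean",
) -> tuple[pd.DataFrame, AnalysisReport]:
    """Run the pipeline on an in-memory synthetic dataset.

    ``use_planted_distances`` bypasses sequence re-estimation and feeds the
    generator's planted distances directly (useful when the correction step
    itself is not under study).
    """
    if use_planted_distances or not ds.pairs:
        distances = ds.ground_truth["planted_distance"].to_dict()
    else:
        distances = {
            r.protein_id: r.kimura_distance for r in batch_distances(ds.pairs)
        }
    features = assemble_features(
        ds.network,
        annotation=ds.annotation,
        catalog=ds.catalog,
        expression=ds.expression.to_dict(),
        distances=distances,
        func_cutoff=func_cutoff,
        clust_cutoff=clust_cutoff,
    )
    return features, analyze(features)


def _fmt(x: Optional[float], digits: int = 4) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    return f"{x:.{digits}g}"


def report_tables(report: AnalysisReport) -> dict[str, str]:
    """Render the report as flat TSV tables (one string per table)."""
    tables: dict[str, str] = {}

    lines = ["x\ty\tcontrols\trho\tp_value\tn"]
    for c in report.correlations + report.partial_correlations:
        lines.append(
            f"{c.x_name}\t{c.y_name}\t{','.join(c.controls) or '-'}\t"
            f"{_fmt(c.rho)}\t{_fmt(c.p_value)}\t{c.n}"
        )
    if len(lines) == 1:
        lines.append("not computed\t\t\t\t\t")
    tables["correlations"] = "\n".join(lines) + "\n"

    lines = ["predictor\tcoefficient\tstd_error\tt\tp_value"]
    if report.regression is None:
        lines.append("not computed\t\t\t\t")
    else:
        for p in report.regression.predictors:
            lines.append(
                f"{p.name}\t{_fmt(p.coefficient)}\t{_fmt(p.std_error)}\t"
                f"{_fmt(p.t_value)}\t{_fmt(p.p_value)}"
            )
        lines.append(f"# n = {report.regression.n}, R^2 = {_fmt(report.regression.r_squared)}")
    tables["regression"] = "\n".join(lines) + "\n"

    lines = ["component\teigenvalue\tvariance_fraction\tretained\t" ]
    if report.pca is None:
        lines = ["not computed"]
    else:
        lines = [
            "component\teigenvalue\tvariance_fraction\tretained\t"
            + "\t".join(f"loading[{v}]" for v in report.pca.variable_names)
        ]
        for j in range(len(report.pca.eigenvalues)):
            row = [
                f"PC{j + 1}",
                _fmt(float(report.pca.eigenvalues[j])),
                _fmt(float(report.pca.variance_fractions[j])),
                str(bool(report.pca.retained[j])),
            ] + [_fmt(float(report.pca.loadings[i, j])) for i in range(len(report.pca.variable_names))]
            lines.append("\t".join(row))
        if report.pc1_distance_correlation is not None:
            c = report.pc1_distance_correlation
            lines.append(f"# Spearman(PC1, distance) rho = {_fmt(c.rho)}, p = {_fmt(c.p_value)}, n = {c.n}")
    tables["pca"] = "\n".join(lines) + "\n"

    lines = ["comparison\tgroup_a\tn_a\tmean_a\tgroup_b\tn_b\tmean_b\tU\tp_value"]
    if not report.group_tests:
        lines.append("not computed\t\t\t\t\t\t\t\t")
    else:
        for key, g in report.group_tests.items():
            lines.append(
                f"{key}\t{g.group_names[0]}\t{g.group_sizes[0]}\t{_fmt(g.group_means[0])}\t"
                f"{g.group_names[1]}\t{g.group_sizes[1]}\t{_fmt(g.group_means[1])}\t"
                f"{_fmt(g.u_statistic)}\t{_fmt(g.p_value)}"
            )
    tables["group_tests"] = "\n".join(lines) + "\n"
    return tables
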