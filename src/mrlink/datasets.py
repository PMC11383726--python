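"""Published reference coefficient tables for worked examples.

Summary-level IVW estimates from a published two-sample MR study of
circulating inflammatory cytokines, blood metabolites and hepatic
fibrosis (FinnGen hepatic-fibrosis outcome, 91-cytokine panel, 1400
blood metabolites). Three tables are bundled:

* cytokine -> hepatic fibrosis (the three IVW-significant cytokines),
* cytokine -> metabolite (the five screened mediator candidates),
* metabolite -> hepatic fibrosis (the 46 IVW-significant metabolites).

Effects on binary outcomes are log-odds; where a source table prints OR
and 95% CI but no SE, the loader derives ``se = (ln hi - ln lo)/3.92``
and, where beta itself is unprinted, ``beta = ln OR``. These tables are
the inputs for the mediation worked examples and the OR/CI reporting
fixtures; they are published estimates, not outputs of this package.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

__all__ = [
    "load_cytokine_fibrosis",
    "load_cytokine_metabolite",
    "load_metabolite_fibrosis",
    "mediation_candidates",
]

_CYTOKINE_FIBROSIS = """\
exposure	or	ci_low	ci_high	pval
MCP-4	1.840	1.014	3.336	0.045
NRTN	2.196	1.204	4.004	0.010
PD-L1	0.455	0.223	0.928	0.030
"""

_CYTOKINE_METABOLITE = """\
exposure	mediator	beta	or	ci_low	ci_high	pval
NRTN	1-linoleoyl-GPE (18:2) levels	-0.127	0.881	0.799	0.971	0.011
NRTN	Laurate (12:0) levels	0.104	1.110	1.007	1.223	0.035
NRTN	Adenosine 5'-diphosphate (ADP) to tyrosine ratio	-0.197	0.821	0.721	0.935	0.003
NRTN	Hypotaurine to cysteine ratio	-0.103	0.902	0.815	0.999	0.047
PD-L1	1-palmitoyl-2-linoleoyl-GPI (16:0/18:2) levels	0.104	1.110	1.015	1.213	0.022
"""

_METABOLITE_FIBROSIS = """\
mediator	nsnp	beta	se	or	ci_low	ci_high	pval
2-hydroxyoctanoate levels	22	-0.477	0.214	0.621	0.408	0.944	0.026
Tauro-beta-muricholate levels	26	-0.342	0.152	0.711	0.528	0.957	0.024
Stearidonate (18:4n3) levels	26	-0.790	0.317	0.454	0.244	0.844	0.013
Gamma-glutamylmethionine levels	25	-0.681	0.298	0.506	0.282	0.907	0.022
3-(3-amino-3-carboxypropyl)uridine levels	17	-0.757	0.375	0.469	0.225	0.979	0.044
2-hydroxy-3-methylvalerate levels	30	-0.556	0.274	0.573	0.335	0.981	0.042
1-linoleoyl-GPE (18:2) levels	33	0.582	0.208	1.789	1.190	2.691	0.005
1-palmitoyl-2-linoleoyl-GPE (16:0/18:2) levels	25	0.403	0.163	1.496	1.086	2.060	0.014
2-hydroxyglutarate levels	28	-0.572	0.273	0.565	0.331	0.964	0.036
S-methylcysteine sulfoxide levels	21	0.890	0.397	2.434	1.118	5.299	0.025
N-acetylcarnosine levels	28	-0.381	0.187	0.683	0.473	0.986	0.042
1-palmitoyl-2-palmitoleoyl-gpc (16:0/16:1) levels	23	0.775	0.302	2.170	1.202	3.918	0.010
1-palmitoyl-2-docosahexaenoyl-gpc (16:0/22:6) levels	23	-0.773	0.277	0.461	0.268	0.794	0.005
1-stearoyl-2-linoleoyl-GPI (18:0/18:2) levels	28	0.524	0.239	1.689	1.058	2.696	0.028
1-(1-enyl-palmitoyl)-2-linoleoyl-GPE (P-16:0/18:2) levels	22	0.681	0.292	1.976	1.114	3.505	0.020
1-oleoyl-2-linoleoyl-GPE (18:1/18:2) levels	33	0.591	0.177	1.807	1.277	2.556	0.001
N-stearoyl-sphingadienine (d18:2/18:0) levels	21	-0.419	0.205	0.658	0.440	0.983	0.041
2-furoylcarnitine levels	22	0.981	0.277	2.666	1.548	4.590	0.000
Carotene diol (3) levels	27	0.702	0.248	2.018	1.241	3.280	0.005
Pentose acid levels	22	0.695	0.349	2.004	1.012	3.968	0.046
Methyl indole-3-acetate levels	22	-0.674	0.288	0.509	0.289	0.897	0.019
1-palmitoyl-2-linoleoyl-GPI (16:0/18:2) levels	24	0.739	0.276	2.093	1.219	3.594	0.007
N-formylmethionine levels	21	-0.765	0.336	0.465	0.241	0.900	0.023
2-hydroxyhippurate (salicylurate) levels	26	0.688	0.321	1.989	1.060	3.731	0.032
Cystine levels	18	-0.821	0.408	0.440	0.198	0.979	0.044
X-11632 levels	25	-0.604	0.296	0.547	0.306	0.976	0.041
X-12544 levels	23	0.828	0.282	2.289	1.317	3.978	0.003
X-17010 levels	19	-0.707	0.343	0.493	0.252	0.966	0.039
X-24344 levels	16	0.792	0.287	2.208	1.258	3.875	0.006
X-24337 levels	28	0.491	0.236	1.634	1.028	2.597	0.038
X-25957 levels	20	0.815	0.367	2.260	1.100	4.643	0.026
X-25420 levels	15	-1.052	0.282	0.349	0.201	0.606	0.000
1-palmitoyl-2-arachidonoyl-gpc (16:0/20:4n6) levels	31	-0.326	0.158	0.722	0.529	0.984	0.039
X-19141 levels	25	0.493	0.236	1.637	1.030	2.600	0.037
Adenosine 5'-diphosphate (ADP) to tyrosine ratio	22	0.395	0.200	1.484	1.002	2.197	0.049
Cortisone to cortisol ratio	20	-0.689	0.345	0.502	0.255	0.988	0.046
Methionine to methionine sulfoxide ratio	27	0.628	0.303	1.873	1.034	3.391	0.038
Oleoyl-linoleoyl-glycerol (18:1 to 18:2) [2] to linoleoyl-arachidonoyl-glycerol (18:2 to 20:4) [2] ratio	28	0.413	0.181	1.511	1.061	2.153	0.022
Adenosine 5'-monophosphate (AMP) to citrate ratio	23	-0.658	0.328	0.518	0.272	0.985	0.045
Hypotaurine to cysteine ratio	34	-0.678	0.315	0.508	0.274	0.942	0.031
Retinol (Vitamin A) to linoleoyl-arachidonoyl-glycerol (18:2 to 20:4) [1] ratio	24	0.573	0.235	1.774	1.118	2.813	0.015
Phosphate to EDTA ratio	20	0.860	0.384	2.363	1.112	5.019	0.025
Cytidine to N-acetylneuraminate ratio	28	0.687	0.289	1.988	1.129	3.502	0.017
Phosphoethanolamine to choline ratio	22	0.762	0.364	2.143	1.049	4.376	0.036
Caffeine to linoleate (18:2n6) ratio	14	-0.740	0.334	0.477	0.248	0.919	0.027
Salicylate to taurocholate ratio	23	0.961	0.349	2.615	1.320	5.178	0.006
"""

#: the four mediator candidates that passed both screening steps,
#: as (exposure, mediator) keys into the two tables above
MEDIATION_CANDIDATES = [
    ("NRTN", "1-linoleoyl-GPE (18:2) levels"),
    ("NRTN", "Adenosine 5'-diphosphate (ADP) to tyrosine ratio"),
    ("NRTN", "Hypotaurine to cysteine ratio"),
    ("PD-L1", "1-palmitoyl-2-linoleoyl-GPI (16:0/18:2) levels"),
]


def _read(text: str) -> pd.DataFrame:
    return pd.read_csv(io.StringIO(text), sep="\t")


def _se_from_ci(lo: pd.Series, hi: pd.Series) -> pd.Series:
    return (np.log(hi) - np.log(lo)) / (2 * 1.96)


def load_cytokine_fibrosis() -> pd.DataFrame:
    """IVW cytokine -> hepatic fibrosis estimates (log-odds beta and SE
    derived from the printed OR and CI)."""
    t = _read(_CYTOKINE_FIBROSIS)
    t["beta"] = np.log(t["or"])
    t["se"] = _se_from_ci(t["ci_low"], t["ci_high"])
    return t


def load_cytokine_metabolite() -> pd.DataFrame:
    """IVW cytokine -> metabolite estimates (SE derived from the CI)."""
    t = _read(_CYTOKINE_METABOLITE)
    t["se"] = _se_from_ci(t["ci_low"], t["ci_high"])
    return t


def load_metabolite_fibrosis() -> pd.DataFrame:
    """IVW metabolite -> hepatic fibrosis estimates (printed beta and SE)."""
    return _read(_METABOLITE_FIBROSIS)


def mediation_candidates() -> pd.DataFrame:
    """The four exposure-mediator pathways with all three coefficient
    sets joined: beta1/se1 (cytokine -> metabolite), beta2/se2
    (metabolite -> fibrosis) and beta_all/se_all (cytokine -> fibrosis)."""
    step1 = load_cytokine_metabolite().set_index(["exposure", "mediator"])
    step2 = load_metabolite_fibrosis().set_index("mediator")
    total = load_cytokine_fibrosis().set_index("exposure")
    rows = []
    for exposure, mediator in MEDIATION_CANDIDATES:
        s1 = step1.loc[(exposure, mediator)]
        s2 = step2.loc[mediator]
        t = total.loc[exposure]
        rows.append(
            {
                "exposure": exposure,
                "mediator": mediator,
                "beta1": float(s1["beta"]),
                "se1": float(s1["se"]),
                "beta2": float(s2["beta"]),
                "se2": float(s2["se"]),
                "beta_all": float(t["beta"]),
                "se_all": float(t["se"]),
            }
        )
    return pd.DataFrame(rows)
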