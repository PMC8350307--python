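# Default knowledge base: EPOS 2012 criteria for rhinosinusitis.
#
# `facts` declares the derivable fact tokens. Rule antecedents may name a
# declared fact or one of the built-in clinical predicates evaluated on a
# patient profile (course_acute, course_chronic, temporal_criterion,
# signs_ge_3, polyps_absent, ige_low, refractory_incs, postop_complication).
#
# All diagnosis facts consistent with a profile are derived; the engine then
# resolves the single category by clinical precedence (complication and
# bacterial disease outrank their baseline categories). Lower priority fires
# first in the log.
facts:
  - dx_common_cold
  - dx_post_viral
  - dx_abrs
  - dx_crs
  - dx_crs_macrolide
  - dx_crs_complication

rules:
  - id: acute-bacterial
    priority: 10
    if: [course_acute, temporal_criterion, signs_ge_3]
    then: dx_abrs
  - id: acute-post-viral
    priority: 20
    if: [course_acute, temporal_criterion]
    then: dx_post_viral
  - id: acute-common-cold
    priority: 30
    if: [course_acute]
    then: dx_common_cold
  - id: chronic-postop-complication
    priority: 10
    if: [course_chronic, postop_complication]
    then: dx_crs_complication
  - id: chronic-macrolide-trial
    priority: 20
    if: [course_chronic, refractory_incs, polyps_absent, ige_low]
    then: dx_crs_macrolide
  - id: chronic-baseline
    priority: 30
    if: [course_chronic]
    then: dx_crs
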