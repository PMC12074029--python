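# Mouse ROI hierarchy: nine major divisions containing 31 subregions.
#
# Abbreviations follow the Allen Mouse Brain CCFv3 naming where a published
# abbreviation is known (MO, ACA, GU, VIS, Str, PTLp, CC, ILA, Mbmot, AUD,
# TEa, CA3, ECT, HPF, CTXsp1, VENT, DORpm, MEZ, SSs).  The remaining
# subregions are CCFv3-plausible placeholder labels completing the
# 9-division / 31-subregion structure; they are placeholders, not a claim
# about the original ROI list.
name: mouse31
divisions:
  Isocortex:
    - {abbr: MO,     name: Somatomotor areas}
    - {abbr: SSp,    name: Primary somatosensory area}        # placeholder
    - {abbr: SSs,    name: Supplemental somatosensory area}
    - {abbr: GU,     name: Gustatory areas}
    - {abbr: VISC,   name: Visceral area}                     # placeholder
    - {abbr: AUD,    name: Auditory areas}
    - {abbr: VIS,    name: Visual areas}
    - {abbr: ACA,    name: Anterior cingulate area}
    - {abbr: PL,     name: Prelimbic area}                    # placeholder
    - {abbr: ILA,    name: Infralimbic area}
    - {abbr: ORB,    name: Orbital area}                      # placeholder
    - {abbr: PTLp,   name: Posterior parietal association areas}
    - {abbr: TEa,    name: Temporal association areas}
    - {abbr: ECT,    name: Ectorhinal area}
    - {abbr: RSP,    name: Retrosplenial area}                # placeholder
  Olfactory areas:
    - {abbr: MOB,    name: Main olfactory bulb}               # placeholder
    - {abbr: PIR,    name: Piriform area}                     # placeholder
  Hippocampal formation:
    - {abbr: HPF,    name: Hippocampal formation (other)}
    - {abbr: CA3,    name: Field CA3}
  Cortical subplate:
    - {abbr: CTXsp1, name: Cortical subplate 1}
    - {abbr: CLA,    name: Claustrum}                         # placeholder
  Cerebral nuclei:
    - {abbr: Str,    name: Striatum}
    - {abbr: PAL,    name: Pallidum}                          # placeholder
  Thalamus:
    - {abbr: VENT,   name: Ventral group of the dorsal thalamus}
    - {abbr: DORpm,  name: Polymodal association cortex related thalamus}
    - {abbr: DORsm,  name: Sensory-motor cortex related thalamus}  # placeholder
  Hypothalamus:
    - {abbr: MEZ,    name: Hypothalamic medial zone}
    - {abbr: LZ,     name: Hypothalamic lateral zone}         # placeholder
  Midbrain and pons:
    - {abbr: Mbmot,  name: Midbrain motor related}
    - {abbr: P,      name: Pons}                              # placeholder
  Fiber tracts:
    - {abbr: CC,     name: Corpus callosum}
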