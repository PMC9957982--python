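{
  "version": "1.0",
  "notes": "20-chunk / 62-branch cerebral arterial nomenclature. Chunk codes: A0-A10 anterior circulation, P0-P8 posterior circulation; odd serial = right, even serial = left, 0 = midline. Branch identifiers are <chunk>.<2-digit index>; chunks owning a single branch use the bare chunk code as the branch code. Entries marked provisional cover conventional vessels whose exact segment-digit membership is not fixed by convention; edit this resource to re-map them.",
  "chunks": [
    {"code": "A0", "name": "anterior communicating artery (ACOA)", "side": "midline"},
    {"code": "A1", "name": "right internal carotid artery branches", "side": "right"},
    {"code": "A2", "name": "left internal carotid artery branches", "side": "left"},
    {"code": "A3", "name": "right anterior basal MCA", "side": "right"},
    {"code": "A4", "name": "left anterior basal MCA", "side": "left"},
    {"code": "A5", "name": "right anterior basal ACA", "side": "right"},
    {"code": "A6", "name": "left anterior basal ACA", "side": "left"},
    {"code": "A7", "name": "right anterior pial MCA", "side": "right"},
    {"code": "A8", "name": "left anterior pial MCA", "side": "left"},
    {"code": "A9", "name": "right anterior pial ACA", "side": "right"},
    {"code": "A10", "name": "left anterior pial ACA", "side": "left"},
    {"code": "P0", "name": "basilar artery (BA)", "side": "midline"},
    {"code": "P1", "name": "right vertebral artery (VA)", "side": "right"},
    {"code": "P2", "name": "left vertebral artery (VA)", "side": "left"},
    {"code": "P3", "name": "right posterior basal PCA", "side": "right"},
    {"code": "P4", "name": "left posterior basal PCA", "side": "left"},
    {"code": "P5", "name": "right posterior pial PCA", "side": "right"},
    {"code": "P6", "name": "left posterior pial PCA", "side": "left"},
    {"code": "P7", "name": "right SCA, AICA, and PICA", "side": "right"},
    {"code": "P8", "name": "left SCA, AICA, and PICA", "side": "left"}
  ],
  "mirror_pairs": [
    ["A1", "A2"], ["A3", "A4"], ["A5", "A6"], ["A7", "A8"], ["A9", "A10"],
    ["P1", "P2"], ["P3", "P4"], ["P5", "P6"], ["P7", "P8"]
  ],
  "branches": [
    {"code": "A0", "name": "anterior communicating artery"},
    {"code": "A1.01", "name": "right internal carotid artery trunk"},
    {"code": "A1.02", "name": "right ophthalmic artery (OA)"},
    {"code": "A1.03", "name": "right anterior choroidal artery (ACHA)"},
    {"code": "A2.01", "name": "left internal carotid artery trunk"},
    {"code": "A2.02", "name": "left ophthalmic artery (OA)"},
    {"code": "A2.03", "name": "left anterior choroidal artery (ACHA)"},
    {"code": "A3.01", "name": "right sphenoidal MCA (M1)"},
    {"code": "A3.02", "name": "right superior division of MCA (MCAS)"},
    {"code": "A3.03", "name": "right inferior division of MCA (MCAI)"},
    {"code": "A4.01", "name": "left sphenoidal MCA (M1)"},
    {"code": "A4.02", "name": "left superior division of MCA (MCAS)"},
    {"code": "A4.03", "name": "left inferior division of MCA (MCAI)"},
    {"code": "A5.01", "name": "right horizontal pre-communicating ACA (A1)"},
    {"code": "A5.02", "name": "right vertical post-communicating pre-callosal ACA (A2)"},
    {"code": "A5.03", "name": "right A1-A2 coalescence (A1A2)", "provisional": true},
    {"code": "A6.01", "name": "left horizontal pre-communicating ACA (A1)"},
    {"code": "A6.02", "name": "left vertical post-communicating pre-callosal ACA (A2)"},
    {"code": "A6.03", "name": "left A1-A2 coalescence (A1A2)", "provisional": true},
    {"code": "A7.01", "name": "right lateral orbitofrontal MCA (MCALO)"},
    {"code": "A7.02", "name": "right pre-Rolandic MCA (MCAPR)"},
    {"code": "A7.03", "name": "right Rolandic MCA (MCAR)"},
    {"code": "A7.04", "name": "right anterior parietal MCA (MCAAP)"},
    {"code": "A7.05", "name": "right posterior parietal MCA (MCAPP)"},
    {"code": "A7.06", "name": "right angular MCA (MCAA)"},
    {"code": "A7.07", "name": "right posterior temporal MCA (MCAPT)"},
    {"code": "A7.08", "name": "right middle temporal MCA (MCAMT)"},
    {"code": "A7.09", "name": "right anterior temporal MCA (MCAAT)"},
    {"code": "A8.01", "name": "left lateral orbitofrontal MCA (MCALO)"},
    {"code": "A8.02", "name": "left pre-Rolandic MCA (MCAPR)"},
    {"code": "A8.03", "name": "left Rolandic MCA (MCAR)"},
    {"code": "A8.04", "name": "left anterior parietal MCA (MCAAP)"},
    {"code": "A8.05", "name": "left posterior parietal MCA (MCAPP)"},
    {"code": "A8.06", "name": "left angular MCA (MCAA)"},
    {"code": "A8.07", "name": "left posterior temporal MCA (MCAPT)"},
    {"code": "A8.08", "name": "left middle temporal MCA (MCAMT)"},
    {"code": "A8.09", "name": "left anterior temporal MCA (MCAAT)"},
    {"code": "A9.01", "name": "right callosomarginal ACA (ACAC)"},
    {"code": "A9.02", "name": "right pericallosal ACA (ACAP)"},
    {"code": "A10.01", "name": "left callosomarginal ACA (ACAC)"},
    {"code": "A10.02", "name": "left pericallosal ACA (ACAP)"},
    {"code": "P0", "name": "basilar artery"},
    {"code": "P1", "name": "right vertebral artery"},
    {"code": "P2", "name": "left vertebral artery"},
    {"code": "P3.01", "name": "right pre/post-communicating PCA (P1P2)"},
    {"code": "P3.02", "name": "right posterior communicating artery (PCOA)"},
    {"code": "P4.01", "name": "left pre/post-communicating PCA (P1P2)"},
    {"code": "P4.02", "name": "left posterior communicating artery (PCOA)"},
    {"code": "P5.01", "name": "right quadrigeminal/calcarine PCA mixture (P3P4)"},
    {"code": "P5.02", "name": "right parieto-occipital artery (PO)"},
    {"code": "P5.03", "name": "right calcarine artery (PCALC)"},
    {"code": "P5.04", "name": "right anterior temporal PCA (PCAAT)"},
    {"code": "P5.05", "name": "right posterior temporal PCA (PCAPT)"},
    {"code": "P6.01", "name": "left quadrigeminal/calcarine PCA mixture (P3P4)"},
    {"code": "P6.02", "name": "left parieto-occipital artery (PO)"},
    {"code": "P6.03", "name": "left calcarine artery (PCALC)"},
    {"code": "P6.04", "name": "left anterior temporal PCA (PCAAT)"},
    {"code": "P6.05", "name": "left posterior temporal PCA (PCAPT)"},
    {"code": "P7.01", "name": "right superior cerebellar artery (SCA)", "provisional": true},
    {"code": "P7.02", "name": "right posterior inferior cerebellar artery (PICA)", "provisional": true},
    {"code": "P8.01", "name": "left superior cerebellar artery (SCA)", "provisional": true},
    {"code": "P8.02", "name": "left posterior inferior cerebellar artery (PICA)", "provisional": true}
  ]
}
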