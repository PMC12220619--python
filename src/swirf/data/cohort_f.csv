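species,f_pre,f_post_d1,f_post_d2,f_post_combined
Ae. cinereus,0.0240,0.0641,0.0262,0.0559
Ae. vexans,0.0163,0.0438,0.0267,0.0347
An. punctipennis,0.1019,0.0644,0.0502,0.0588
An. quadrimaculatus,0.0513,0.0127,0.0626,0.0482
Cq. perturbans,0.0078,0.0165,0.0120,0.0149
Cs. melanura,0.0187,0.0651,0.0315,0.0465
Cx. pipiens/restuans,0.0031,0.0612,0.0690,0.0666
Oc. abserratus,0.0106,0.0673,0.0174,0.0419
Oc. canadensis,0.0024,0.0046,0.0033,0.0038
Oc. excrucians,0.0018,0.0022,0.0261,0.0033
Ps. ferox,0.0951,0.0942,0.0624,0.0914
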