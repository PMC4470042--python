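# Example landmark-template definition (long format accepted by `bonetrack register --landmarks`).
# The six classic tarsal template sites; pixel values here are illustrative placeholders
# to be replaced with positions picked on the first frame of a real acquisition.
frame0,view,landmark_name,u,v,bone
0,L,navicular_anterodorsal,412,238,navicular
0,R,navicular_anterodorsal,265,231,navicular
0,L,talus_anterodorsal,365,210,talus
0,R,talus_anterodorsal,300,205,talus
0,L,talus_posterior,258,226,talus
0,R,talus_posterior,398,222,talus
0,L,calcaneal_tuberosity_superior,232,247,calcaneus
0,R,calcaneal_tuberosity_superior,421,244,calcaneus
0,L,calcaneal_tuberosity_posterior,205,272,calcaneus
0,R,calcaneal_tuberosity_posterior,447,268,calcaneus
0,L,calcaneal_tuberosity_inferior,221,301,calcaneus
0,R,calcaneal_tuberosity_inferior,430,297,calcaneus
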