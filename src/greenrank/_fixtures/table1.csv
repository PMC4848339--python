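procedure_id,technique,nemi,eco_scale,reference
1,Ultrasonic solid-liquid extraction-thin-layer chromatography-high-performance liquid chromatography-diode array detection/ultraviolet detection,2,72,21
2,Ultrasonic solid-liquid extraction-high-performance liquid chromatography-programmable fluorescence detection,1,51,22
3,Ultrasonic solid-liquid extraction-high-performance liquid chromatography-programmable fluorescence detection,2,62,23
4,Ultrasonic micellar extraction-high performance liquid chromatography-ultraviolet detection,4,77,24
5,Vortex-assisted extraction-dispersive liquid-liquid microextraction-high-performance liquid chromatography-fluorescence detection,2,81,25
6,Ultrasonic-assisted extraction-matrix solid-phase dispersion-high-performance liquid chromatography-ultraviolet detection,2,89,26
7,Focused ultrasonic solid-liquid extraction-high-performance liquid chromatography-fluorescence detection,3,86,11
8,Micro focused ultrasonic solid-liquid extraction-high-performance liquid chromatography-fluorescence detection,2,83,27
9,Miniaturized homogenous liquid-liquid extraction-high-performance liquid chromatography-fluorescence detection,2,51,28
10,Microwave-assisted extraction-solid-phase extraction-liquid chromatography-photodiode array detection-mass spectrometry,2,59,29
11,In situ microwave-assisted extraction-high-performance liquid chromatography-photodiode array detection,2,81,30
12,Microwave-assisted extraction-high-performance liquid chromatography-ultraviolet detection,3,78,24
13,Microwave-assisted extraction-high performance liquid chromatography-fluorescence detection,2,61,31
14,Microwave-assisted extraction-gas chromatography-mass spectrometry,2,60,32
15,Microwave-assisted extraction-2-dimensional gas chromatography-time-of-flight mass spectrometry,2,56,33
16,Microwave-assisted extraction-gas chromatography-mass spectrometry,2,53,34
17,Soxhlet extraction-gas chromatography-mass spectrometry,1,63,
18,Microwave-assisted extraction-gas chromatography-mass spectrometry,2,74,35
19,Soxhlet extraction-gas chromatography-mass spectrometry,2,68,
20,Accelerated solvent extraction-supercritical fluid extraction-gas chromatography-mass spectrometry,2,83,36
21,Focused ultrasonic solid-liquid extraction-gas chromatography-mass spectrometry,2,65,37
22,Microwave-assisted solid-phase extraction-gas chromatography-mass spectrometry,2,75,38
23,Microwave-assisted headspace solid-phase microextraction-gas chromatography-tandem mass spectrometry,4,92,39
24,Microwave-assisted micellar solid-phase microextraction-gas chromatography-mass spectrometry,3,93,40
25,Pressurized hot water extraction-solid-phase microextraction-gas chromatography-mass spectrometry,4,90,41
26,Pressurized liquid extraction-stir bar sorptive extraction-thermal desorption-gas chromatography-triple quadrupole mass spectrometry,2,77,42
27,Pressurized liquid extraction-solid-phase extraction-gas chromatography-mass spectrometry,2,68,43
28,Pressurized liquid extraction-gas chromatography-mass spectrometry,2,69,44
29,Pressurized liquid extraction-large-volume injection-gas chromatography-mass spectrometry,2,86,45
30,Programmed temperature vaporization-gas chromatography-mass spectrometry,2,60,46
31,Solid-phase extraction-gas chromatography-mass spectrometry/selected ion storage,2,84,9
32,Solid-phase extraction-gas chromatography-quadrupole ion trap mass spectrometry,2,81,47
33,Solid-liquid extraction-gas chromatography-tandem mass spectrometry-pseudo multiple reaction monitoring,3,90,48
34,Ultrasonic solid-liquid extraction-solid-phase extraction-gas chromatography-mass spectrometry,2,68,49
35,Ultrasonic solid-liquid extraction-gas chromatography-mass spectrometry,2,62,50
36,Ultrasonic solid-liquid extraction-gas chromatography-mass spectrometry,2,53,10
37,Ultrasonic solid-liquid extraction-gas chromatography-mass spectrometry,2,74,4
38,Ultrasonic solid-liquid extraction-stir bar sorptive extraction-thermal desorption-gas chromatography-mass spectrometry,2,55,51
39,Ultrasonic solid-liquid extraction-gas chromatography-electron ionization tandem mass spectrometry,2,60,52
40,Ultrasonic solid-liquid extraction-thin-layer chromatography-gas chromatography-ion trap mass spectrometry,2,60,21
41,Online dynamic microwave-assisted extraction-solid-phase extraction-gas chromatography-mass spectrometry,2,67,53
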