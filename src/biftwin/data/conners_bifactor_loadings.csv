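item,label,subscale,general,inattention,hyperactivity
1,Struggles paying attention,inattention,0.53,0.50,0.04
2,Makes mistakes,inattention,0.40,0.38,0.01
3,Struggles focusing on tasks,inattention,0.59,0.57,0.02
4,Struggles focusing on conversations,inattention,0.56,0.50,0.06
5,Struggles following instructions,inattention,0.56,0.52,0.04
6,Struggles finishing tasks,inattention,0.52,0.55,-0.03
7,Struggles with organisation,inattention,0.46,0.53,-0.07
8,Dislikes complex tasks,inattention,0.34,0.38,-0.04
9,Loses things,inattention,0.47,0.38,0.09
10,Gets distracted,inattention,0.59,0.46,0.13
11,Forgets things,inattention,0.50,0.47,0.03
12,Struggles sitting still,hyperactivity,0.53,0.14,0.39
13,Leaves seat inappropriately,hyperactivity,0.57,0.19,0.38
14,Feels restless,hyperactivity,0.56,0.19,0.36
15,Struggles remaining quiet,hyperactivity,0.58,0.10,0.48
16,Prefers being on the go,hyperactivity,0.29,-0.08,0.37
17,Talks too much,hyperactivity,0.41,-0.13,0.54
18,Blurts out answers to questions,hyperactivity,0.47,-0.09,0.56
19,Struggles waiting turns,hyperactivity,0.53,-0.03,0.55
20,Interrupts others,hyperactivity,0.45,-0.02,0.48
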