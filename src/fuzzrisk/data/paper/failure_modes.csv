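fm_id,description,cause,effect,occurrence,severity,detection,output_label,output_crisp
FM1,Irregular consumption of immunosuppressive drugs,Failure on the part of the recipient to follow medical advice,Rejection of transplant / reduction of quality of transplanted organ,Very High,Dangerous without warning,Low,VH,0.930
FM2,Possibility of post-transplant diseases,Taking anti-transplant rejection drugs,Rejection of the transplant / reduction of the quality of the transplanted organ / death of the recipient,Moderate,Very High,Moderate,VH,0.911
FM3,Ignoring post-transplant quarantine rules,Failure on the part of the recipient to follow medical advice,Rejection of transplant / reduction of quality of transplanted organ,Moderate,Very High,Moderate,VH,0.911
FM4,Error in medical research before transplantation,Negligence of the laboratory and the transplant team member,Rejection of the transplant / reduction of the quality of the transplanted organ / death of the recipient,Low,Dangerous with warnings,Moderate,H,0.750
FM5,Donor creatine levels,"Decreased blood flow, dehydration, diet",Rejection of the transplant / reduction of the quality of the transplanted organ / death of the recipient,High,High,M,H,0.750
FM6,The ischemic time of the transplanted organ has elapsed,Mismanagement planning and type of organ allocation in network,Rejection of the transplant / reduction of the quality of the transplanted organ / death of the recipient,High,Very High,Low,VH,0.750
FM7,Do heavy work after transplantation,Failure on the part of the recipient to follow medical advice,Rejection of transplant / reduction of quality of transplanted organ,Remote,High,Moderate,H,0.750
FM8,Mental illness,Patients' conscience agony,Rejection of transplant / reduction of quality of transplanted organ,High,High,Very Low,H,0.750
FM9,Improper diet,Failure on the part of the recipient to follow medical advice,Rejection of transplant / reduction of quality of transplanted organ,High,High,Very Low,H,0.750
FM10,Possibility of oral diseases,Taking anti-transplant rejection drugs,,Moderate,High,Low,L,0.500
FM11,Exposure to harmful sunlight or radiation and skin-cancer treatment burden,,,,,,,
FM12,Cytomegalovirus (CMV) infection after transplantation,,,,,,,
FM13,Contracting viral infections (herpes simplex and respiratory viruses),,,,,,,
FM14,Excessive weight gain,,,,,,,
FM15,Medical errors in the surgical or postoperative process,,,,,,,
FM16,Pregnancy after organ transplantation,,,,,,,
FM17,Prolonged organ storage duration,,,,,,,
FM18,Donor-recipient age incompatibility,,,,,,,
FM19,Compromised physical function after transplantation,,,,,,,
FM20,Insufficient physical activity and restricted mobility,,,,,,,
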